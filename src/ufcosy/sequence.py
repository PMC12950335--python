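"""Pulse-sequence parameters and derived acquisition geometry.

The acquisition is a spatially encoded ("ultrafast") 2D experiment: a pair of
opposed chirp pulses encodes the indirect evolution time along the sample's
z axis, and an echo-planar train of ``2 * N_acq`` bipolar gradient lobes reads
it out.  Interleaving repeats the readout ``N_i`` times with an incremented
pre-acquisition delay, multiplying the conventional-dimension spectral width
by ``N_i``.

All gradient amplitudes are in G/cm and duration fields in seconds unless a
field name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "GAMMA_H",
    "SequenceParams",
    "DerivedTiming",
    "derive_geometry",
    "interleave_delays",
    "t2_grid",
    "interleave_index_map",
    "experiment_duration",
]

#: Proton gyromagnetic ratio in Hz/G.
GAMMA_H = 4257.7


def _default_aux_gradients() -> dict:
    # Carried as provenance only; coherence-selection physics is not simulated.
    return {
        "G_1": {"amplitude_G_per_cm": 31.3, "duration_s": 1e-3},
        "G_2": {"amplitude_G_per_cm": 15.6, "duration_s": 1e-3},
        "G_3": {"amplitude_G_per_cm": 50.1, "duration_s": 800e-6},
        "G_4": {"amplitude_G_per_cm": -50.1, "duration_s": 800e-6},
        "G_5": {"amplitude_G_per_cm": 50.1, "duration_s": 1e-3},
        "G_6": {"amplitude_G_per_cm": -50.1, "duration_s": 1e-3},
    }


@dataclass
class SequenceParams:
    """Acquisition parameters for one interleaved ultrafast COSY experiment."""

    T_chirp: float = 15e-3        # duration of each encoding chirp pulse, s
    sweep: float = 28e3           # chirp sweep range, Hz
    G_e: float = 3.6              # encoding gradient amplitude, G/cm
    G_a: float = 50.1             # acquisition (readout) gradient amplitude, G/cm
    T_a: float = 748e-6           # duration of one acquisition gradient lobe, s
    G_p: float = -21.8            # post-mixing gradient, G/cm (metadata only)
    N_acq: int = 64               # bipolar gradient pairs per transient
    N_i: int = 8                  # interleaved scans
    N_s: int = 32                 # averages per interleave
    N_dummy: int = 4              # dummy transients before acquisition
    recovery: float = 5.0         # recovery delay per transient, s
    t_m: float = 10e-3            # mixing time, s
    larmor: float = 700.28        # 1H Larmor frequency, MHz
    # 256 samples keep the spatial FOV 2*pi*N_k/k_max above the sample
    # length, so the per-lobe echo is adequately sampled; 128 aliases it.
    N_k: int = 256                # complex samples per gradient lobe
    fixed_overhead: float = 6e-3  # per-transient pulses/purge gradients, s
    carrier_ppm: float = 3.0      # transmitter offset used for ppm referencing
    aux_gradients: dict = field(default_factory=_default_aux_gradients)

    def __post_init__(self) -> None:
        for name in ("T_chirp", "sweep", "T_a", "recovery", "t_m", "larmor"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be positive and finite, got {value}")
        if self.N_i < 1:
            raise ValueError("N_i must be >= 1")
        if self.N_acq < 1:
            raise ValueError("N_acq must be >= 1")
        if self.N_k < 8:
            raise ValueError("N_k must be >= 8")
        if self.N_s < 0 or self.N_dummy < 0:
            raise ValueError("scan counts must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceParams":
        return cls(**d)


@dataclass(frozen=True)
class DerivedTiming:
    """Geometry and timing quantities derived from :class:`SequenceParams`.

    Attributes
    ----------
    L : float
        Effective sample length excited by the chirp sweep, m.
    C : float
        Spatiotemporal encoding constant (indirect evolution time per unit
        position), s/m.  Satisfies ``C * L == 2 * T_chirp``.
    k_max : float
        Wavenumber range swept by one acquisition lobe, rad/m.
    SW2 : float
        Conventional-dimension spectral width after interleave merging, Hz.
    f1_span : float
        Frequency span mapped onto the readout axis by the encoding, Hz.
    delays : tuple of float
        Per-interleave pre-acquisition delays, s (first is 0).
    duration : float
        Wall-clock duration of the full experiment, s.
    """

    L: float
    C: float
    k_max: float
    SW2: float
    f1_span: float
    delays: tuple
    duration: float

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "C": self.C,
            "k_max": self.k_max,
            "SW2": self.SW2,
            "f1_span": self.f1_span,
            "delays": list(self.delays),
            "duration": self.duration,
        }


def derive_geometry(p: SequenceParams) -> DerivedTiming:
    """Compute the derived acquisition geometry for a parameter set.

    The sample length is fixed by requiring the chirp sweep to cover exactly
    the frequency spread imposed by the encoding gradient over the sample,
    ``L = sweep / (gamma_H * G_e)``; the constant-time double-chirp convention
    then gives ``C = 2 * T_chirp / L``.
    """
    if p.G_e == 0 or p.G_a == 0:
        raise ValueError("encoding and acquisition gradients must be non-zero")
    # gradients are given in G/cm; lengths are SI (m), hence the factor 100
    L = p.sweep / (GAMMA_H * abs(p.G_e) * 100.0)
    C = 2.0 * p.T_chirp / L
    k_max = 2.0 * math.pi * GAMMA_H * abs(p.G_a) * 100.0 * p.T_a
    f1_span = k_max / (2.0 * math.pi * C)
    SW2 = p.N_i / (2.0 * p.T_a)
    delays = interleave_delays(p.T_a, p.N_i)
    duration = experiment_duration(p)
    return DerivedTiming(
        L=L,
        C=C,
        k_max=k_max,
        SW2=SW2,
        f1_span=f1_span,
        delays=tuple(delays),
        duration=duration,
    )


def interleave_delays(T_a: float, N_i: int) -> list:
    """Pre-acquisition delays ``d_i = i * 2 * T_a / N_i`` for i = 0..N_i-1."""
    if N_i < 1:
        raise ValueError("N_i must be >= 1")
    if T_a <= 0:
        raise ValueError("T_a must be positive")
    return [i * 2.0 * T_a / N_i for i in range(N_i)]


def t2_grid(p: SequenceParams) -> np.ndarray:
    """Merged conventional-dimension time grid for one gradient polarity.

    Merging the same-polarity lobe start times ``2 m T_a + d_i`` over all
    acquisition loops m and interleaves i yields a uniform grid of
    ``N_acq * N_i`` points with dwell ``2 T_a / N_i``.
    """
    delays = np.asarray(interleave_delays(p.T_a, p.N_i))
    lobes = 2.0 * p.T_a * np.arange(p.N_acq)
    times = (lobes[:, None] + delays[None, :]).ravel()
    return np.sort(times)


def interleave_index_map(p: SequenceParams) -> np.ndarray:
    """Interleave index of each point of the merged ``t2_grid`` (period N_i)."""
    delays = np.asarray(interleave_delays(p.T_a, p.N_i))
    lobes = 2.0 * p.T_a * np.arange(p.N_acq)
    times = (lobes[:, None] + delays[None, :]).ravel()
    idx = np.broadcast_to(np.arange(p.N_i)[None, :], (p.N_acq, p.N_i)).ravel()
    return idx[np.argsort(times, kind="stable")]


def experiment_duration(p: SequenceParams) -> float:
    """Total experiment duration in seconds.

    One transient comprises the recovery delay, both encoding chirps, the
    mixing time, the EPSI readout of ``2 * N_acq`` lobes and a small fixed
    overhead for hard pulses and purge gradients.  Dummy transients are
    counted once, on top of the ``N_i * N_s`` acquired transients.
    """
    t_transient = (
        p.recovery
        + 2.0 * p.T_chirp
        + p.t_m
        + 2.0 * p.N_acq * p.T_a
        + p.fixed_overhead
    )
    n_transients = p.N_i * p.N_s + p.N_dummy
    return n_transients * t_transient
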