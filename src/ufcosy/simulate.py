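"""Forward model: spatially encoded EPSI transients from a 2D peak list.

Each resonance contributes an echo along every readout gradient lobe whose
k-space position encodes its indirect frequency (through the encoding
constant C), modulated in the conventional dimension by its direct frequency
and T2 decay.  The finite sample gives the echo a sinc profile
(:func:`profile_transform`).  Per-transient amplitude/phase jitter and an
optional per-interleave systematic modulation feed the interleaving ghost
model; thermal noise is complex Gaussian.

Signal model for transient (interleave i, average s), lobe g with sign
``(-1)**g`` and intra-lobe sample j::

    k(g, j) = -kappa*T_a/2 + sign*kappa*tau_j + kappa*T_a*sum(signs before g)
    s(i,s,g,j) = sum_p A_p * J_p(i,s) * W(k + C*Omega1_p)
                 * exp(1j*Omega2_p*t2) * exp(-t2/T2_p)  + noise

with ``kappa = 2*pi*gamma_H*G_a``, ``tau_j = (j+1/2)*T_a/N_k`` and
``t2 = d_i + g*T_a`` (idealized mode; realistic mode adds ``tau_j``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .mixture import Peak2D
from .sequence import GAMMA_H, DerivedTiming, SequenceParams, derive_geometry

__all__ = [
    "JitterSpec",
    "NoiseSpec",
    "RawUF",
    "profile_transform",
    "simulate_raw",
    "average_scans",
]


@dataclass
class JitterSpec:
    """Scan-to-scan instability of the transients.

    ``amp_sigma`` and ``phase_sigma`` are random per transient;
    ``systematic_amp`` is a fixed per-interleave amplitude deviation (the
    source of N_s-independent ghost artefacts).  All three deviations are
    multiplied by ``solvent_multiplier`` for solvent-class peaks, which
    makes solvent ghosts dominate as observed experimentally.
    """

    amp_sigma: float = 0.0
    phase_sigma: float = 0.0
    systematic_amp: Optional[list] = None
    solvent_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.amp_sigma < 0 or self.phase_sigma < 0:
            raise ValueError("jitter sigmas must be >= 0")
        if self.solvent_multiplier < 1.0:
            raise ValueError("solvent_multiplier must be >= 1")

    def to_dict(self) -> dict:
        return {
            "amp_sigma": self.amp_sigma,
            "phase_sigma": self.phase_sigma,
            "systematic_amp": (
                None if self.systematic_amp is None else list(self.systematic_amp)
            ),
            "solvent_multiplier": self.solvent_multiplier,
        }


@dataclass
class NoiseSpec:
    sigma_thermal: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_thermal < 0:
            raise ValueError("sigma_thermal must be >= 0")

    def to_dict(self) -> dict:
        return {"sigma_thermal": self.sigma_thermal}


@dataclass
class RawUF:
    """Raw interleaved EPSI data: ``data[interleave, average, lobe, sample]``."""

    data: np.ndarray
    params: SequenceParams
    derived: DerivedTiming
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_i, n_s, n_lobes, n_k = self.data.shape
        if n_lobes != 2 * self.params.N_acq:
            raise ValueError("lobe count must equal 2 * N_acq")
        if n_k != self.params.N_k:
            raise ValueError("sample count must equal N_k")
        if n_i != self.params.N_i:
            raise ValueError("interleave count must equal N_i")


def profile_transform(q, L: float):
    """Spatial transform of a unit box sample profile: ``sin(qL/2)/(qL/2)``.

    ``q`` in rad/m, ``L`` the sample length in m; W(0) = 1.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    return np.sinc(np.asarray(q) * L / (2.0 * np.pi))


def _jitter_factors(
    jitter: JitterSpec, params: SequenceParams, rng: np.random.Generator
) -> dict:
    """Per-class complex jitter factor arrays of shape (N_i, N_s)."""
    shape = (params.N_i, max(params.N_s, 1))
    z_amp = rng.standard_normal(shape)
    z_phase = rng.standard_normal(shape)
    sys = np.zeros(params.N_i)
    if jitter.systematic_amp is not None:
        sys = np.asarray(jitter.systematic_amp, dtype=float)
        if sys.shape != (params.N_i,):
            raise ValueError("systematic_amp must have length N_i")
    factors = {}
    for klass, mult in (("regular", 1.0), ("solvent", jitter.solvent_multiplier)):
        amp = (1.0 + mult * jitter.amp_sigma * z_amp) * (1.0 + mult * sys)[:, None]
        phase = np.exp(1j * mult * jitter.phase_sigma * z_phase)
        factors[klass] = amp * phase
    return factors


def simulate_raw(
    peaks: Iterable[Peak2D],
    params: SequenceParams,
    timing: Optional[DerivedTiming] = None,
    jitter: Optional[JitterSpec] = None,
    noise: Optional[NoiseSpec] = None,
    seed: int = 0,
    mode: str = "idealized",
) -> RawUF:
    """Simulate the full interleaved EPSI acquisition of a peak list.

    Parameters
    ----------
    peaks
        (Suppressed) 2D peak list; solvent peaks get amplified jitter.
    mode
        ``idealized`` freezes t2 at the lobe start (the reconstruction's
        oracle surface); ``realistic`` lets it advance within the lobe,
        producing the uncorrected peak shear of a real readout.

    All randomness comes from a single generator seeded with ``seed``;
    identical inputs and seed give bit-identical output.
    """
    if mode not in ("idealized", "realistic"):
        raise ValueError(f"unknown mode {mode!r}")
    peaks = list(peaks)
    if timing is None:
        timing = derive_geometry(params)
    jitter = jitter or JitterSpec()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)

    n_i, n_s = params.N_i, max(params.N_s, 1)
    n_lobes, n_k = 2 * params.N_acq, params.N_k
    kappa = 2.0 * np.pi * GAMMA_H * abs(params.G_a) * 100.0  # rad/(m s)
    tau = (np.arange(n_k) + 0.5) * params.T_a / n_k
    k_even = -kappa * params.T_a / 2.0 + kappa * tau       # ascending sweep
    k_odd = kappa * params.T_a / 2.0 - kappa * tau         # descending sweep
    delays = np.asarray(timing.delays)
    t2 = delays[:, None] + np.arange(n_lobes)[None, :] * params.T_a  # (N_i, G)

    factors = _jitter_factors(jitter, params, rng)
    data = np.zeros((n_i, n_s, n_lobes, n_k), dtype=np.complex128)

    groups = {"regular": [], "solvent": []}
    for p in peaks:
        groups["solvent" if p.klass == "solvent" else "regular"].append(p)

    half_span = timing.f1_span / 2.0
    for klass, group in groups.items():
        if not group:
            continue
        amp = np.array([p.amplitude for p in group])
        f1_hz = np.array(
            [(p.f1 - params.carrier_ppm) * params.larmor for p in group]
        )
        f2_hz = np.array(
            [(p.f2 - params.carrier_ppm) * params.larmor for p in group]
        )
        t2_rates = np.array([1.0 / p.T2 for p in group])
        if np.any(np.abs(f1_hz) > half_span):
            warnings.warn(
                "peak indirect frequency outside the +/- f1_span/2 readout "
                "window; its echo folds outside the sampled k range",
                stacklevel=2,
            )
        omega1 = 2.0 * np.pi * f1_hz
        alpha = 1j * 2.0 * np.pi * f2_hz - t2_rates  # complex evolution rate
        # echo profiles per parity: (P, N_k)
        w_even = profile_transform(
            k_even[None, :] + timing.C * omega1[:, None], timing.L
        ).astype(np.complex128)
        w_odd = profile_transform(
            k_odd[None, :] + timing.C * omega1[:, None], timing.L
        ).astype(np.complex128)
        if mode == "realistic":
            intra = np.exp(alpha[:, None] * tau[None, :])
            w_even = w_even * intra
            w_odd = w_odd * intra
        envelope = amp[:, None, None] * np.exp(
            alpha[:, None, None] * t2[None, :, :]
        )  # (P, N_i, G)
        signal = np.empty((n_i, n_lobes, n_k), dtype=np.complex128)
        signal[:, 0::2, :] = np.einsum(
            "pig,pj->igj", envelope[:, :, 0::2], w_even, optimize=True
        )
        signal[:, 1::2, :] = np.einsum(
            "pig,pj->igj", envelope[:, :, 1::2], w_odd, optimize=True
        )
        data += factors[klass][:, :, None, None] * signal[:, None, :, :]

    if noise.sigma_thermal > 0:
        shape = data.shape
        data += noise.sigma_thermal * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )

    provenance = {
        "n_peaks": len(peaks),
        "seed": seed,
        "mode": mode,
        "jitter": jitter.to_dict(),
        "noise": noise.to_dict(),
        "averaged": False,
    }
    return RawUF(data=data, params=params, derived=timing, provenance=provenance)


def average_scans(raw: RawUF) -> RawUF:
    """Collapse the average axis by its mean (thermal noise shrinks ~1/sqrt(N_s))."""
    if raw.data.shape[1] < 1:
        raise ValueError("no averages to collapse")
    data = raw.data.mean(axis=1, keepdims=True)
    provenance = dict(raw.provenance)
    provenance["averaged"] = True
    provenance["n_averaged"] = raw.data.shape[1]
    return RawUF(
        data=data, params=raw.params, derived=raw.derived, provenance=provenance
    )
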