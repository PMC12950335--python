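"""Reconstruction of interleaved ultrafast raw data into 2D spectra.

Processing chain: split the EPSI lobes by gradient polarity (reversing the
descending sweeps), merge interleaves onto the uniform conventional-time
grid, then along the ultrafast axis do inverse transform -> Gaussian
apodisation in the spatial domain -> zero-fill -> forward transform, and
along the conventional axis apply a half-sine window, zero-fill and
transform.  Polarities are reconstructed separately and their magnitude
spectra summed.  All transforms are unitary (norm="ortho") so energy
bookkeeping is trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .sequence import DerivedTiming, SequenceParams, interleave_delays
from .simulate import RawUF

__all__ = [
    "ProcessingConfig",
    "MergedData",
    "Spectrum2D",
    "split_and_merge",
    "process",
    "calibrate",
    "find_peak",
]


@dataclass
class ProcessingConfig:
    """Knobs of the reconstruction chain.

    ``zerofill`` is (ultrafast, conventional) output sizes; ``gauss_sigma``
    the spatial Gaussian width as a fraction of the spatial extent (None
    disables apodisation); ``polarity`` selects which gradient lobe sets
    contribute.
    """

    zerofill: Tuple[int, int] = (512, 1024)
    gauss_sigma: Optional[float] = 0.25
    sine_window: bool = True
    polarity: str = "both"
    display: str = "magnitude"

    def __post_init__(self) -> None:
        if self.polarity not in ("both", "even", "odd"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.gauss_sigma is not None and self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be positive or None")
        if self.display != "magnitude":
            raise ValueError("only magnitude display is supported")

    def to_dict(self) -> dict:
        return {
            "zerofill": list(self.zerofill),
            "gauss_sigma": self.gauss_sigma,
            "sine_window": self.sine_window,
            "polarity": self.polarity,
            "display": self.display,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProcessingConfig":
        d = dict(d)
        if "zerofill" in d:
            d["zerofill"] = tuple(d["zerofill"])
        return cls(**d)


@dataclass
class MergedData:
    """Per-polarity k x t2 matrices on the uniform merged grid."""

    even: np.ndarray      # (N_k, N_acq * N_i)
    odd: np.ndarray       # (N_k, N_acq * N_i), sample axis already reversed
    t2_even: np.ndarray   # s
    t2_odd: np.ndarray    # s
    params: SequenceParams
    timing: DerivedTiming


@dataclass
class Spectrum2D:
    """Processed magnitude spectrum with ppm axes (decreasing, NMR style)."""

    matrix: np.ndarray
    f1_axis: np.ndarray
    f2_axis: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.f1_axis.size, self.f2_axis.size):
            raise ValueError("matrix shape does not match axes")
        if np.any(self.matrix < 0):
            raise ValueError("magnitude matrix must be non-negative")
        for axis in (self.f1_axis, self.f2_axis):
            if not np.all(np.diff(axis) < 0):
                raise ValueError("axes must be strictly decreasing")

    def index_of(self, f1: float, f2: float) -> Tuple[int, int]:
        """Indices of the grid point nearest to (f1, f2) in ppm."""
        return (
            int(np.argmin(np.abs(self.f1_axis - f1))),
            int(np.argmin(np.abs(self.f2_axis - f2))),
        )


def _merge_polarity(
    lobes: np.ndarray, delays: np.ndarray, T_a: float, offset_lobes: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Order one polarity's (N_i, N_acq, N_k) lobes by conventional time."""
    n_i, n_acq, n_k = lobes.shape
    t2 = (
        delays[:, None]
        + (2 * np.arange(n_acq)[None, :] + offset_lobes) * T_a
    )  # (N_i, N_acq)
    flat = lobes.reshape(n_i * n_acq, n_k)
    t2_flat = t2.ravel()
    order = np.argsort(t2_flat, kind="stable")
    return flat[order].T.copy(), t2_flat[order]


def split_and_merge(raw: RawUF) -> MergedData:
    """Split averaged raw data into polarities on the merged uniform grid.

    Descending-sweep (odd) lobes are reversed along the sample axis so both
    polarities share the same ascending k grid.
    """
    if raw.data.shape[1] != 1:
        raise ValueError("average axis must be collapsed first (average_scans)")
    p = raw.params
    data = raw.data[:, 0]  # (N_i, 2*N_acq, N_k)
    if data.shape[0] != p.N_i:
        raise ValueError("missing interleaves")
    delays = np.asarray(interleave_delays(p.T_a, p.N_i))
    even = data[:, 0::2, :]
    odd = data[:, 1::2, :][:, :, ::-1]  # reverse k sweep direction
    even_m, t2_even = _merge_polarity(even, delays, p.T_a, 0)
    odd_m, t2_odd = _merge_polarity(odd, delays, p.T_a, 1)
    return MergedData(
        even=even_m, odd=odd_m, t2_even=t2_even, t2_odd=t2_odd,
        params=p, timing=raw.derived,
    )


def _process_ultrafast(S: np.ndarray, zf1: int, gauss_sigma) -> np.ndarray:
    """k-axis: inverse transform, spatial Gaussian, centered zero-fill, forward."""
    n_k = S.shape[0]
    if zf1 < n_k:
        raise ValueError("ultrafast zerofill smaller than data")
    spatial = np.fft.fftshift(np.fft.ifft(S, axis=0, norm="ortho"), axes=0)
    if gauss_sigma is not None:
        z = np.arange(n_k) - n_k // 2
        sigma = gauss_sigma * n_k
        spatial = spatial * np.exp(-(z * z) / (2.0 * sigma * sigma))[:, None]
    padded = np.zeros((zf1, S.shape[1]), dtype=np.complex128)
    start = (zf1 - n_k) // 2
    padded[start:start + n_k] = spatial
    return np.fft.fft(np.fft.ifftshift(padded, axes=0), axis=0, norm="ortho")


def _process_conventional(
    S: np.ndarray, zf2: int, sine_window: bool, dwell: float, t_offset: float
) -> Tuple[np.ndarray, np.ndarray]:
    """t2-axis: half-sine window, zero-fill, transform, linear-phase align."""
    m = S.shape[1]
    if zf2 < m:
        raise ValueError("conventional zerofill smaller than data")
    if sine_window:
        S = S * np.sin(np.pi * (np.arange(m) + 0.5) / m)[None, :]
    padded = np.zeros((S.shape[0], zf2), dtype=np.complex128)
    padded[:, :m] = S
    spec = np.fft.fftshift(np.fft.fft(padded, axis=1, norm="ortho"), axes=1)
    freqs = np.fft.fftshift(np.fft.fftfreq(zf2, d=dwell))
    # align the polarity's time origin (no-op for magnitude display)
    return spec * np.exp(-2j * np.pi * freqs * t_offset)[None, :], freqs


def process(
    S: MergedData,
    config: Optional[ProcessingConfig] = None,
    timing: Optional[DerivedTiming] = None,
) -> Spectrum2D:
    """Run the full processing chain on merged data.

    Returns the magnitude spectrum on a (zerofill[0], zerofill[1]) grid with
    ppm axes referenced to the carrier: ``f1 = -k / (2 pi C)`` mapped through
    the Larmor frequency, ``f2`` from the merged-grid spectral width.
    """
    config = config or ProcessingConfig()
    timing = timing or S.timing
    p = S.params
    zf1, zf2 = config.zerofill
    dwell = 2.0 * p.T_a / p.N_i

    parts = []
    if config.polarity in ("both", "even"):
        parts.append((S.even, 0.0))
    if config.polarity in ("both", "odd"):
        parts.append((S.odd, p.T_a))
    total = None
    for matrix, t_offset in parts:
        uf = _process_ultrafast(matrix, zf1, config.gauss_sigma)
        spec, _ = _process_conventional(
            uf, zf2, config.sine_window, dwell, t_offset
        )
        mag = np.abs(spec)
        total = mag if total is None else total + mag

    n_k = p.N_k
    dk = timing.k_max / n_k
    k0 = -timing.k_max / 2.0 + dk / 2.0
    k_axis = k0 + np.arange(zf1) * dk * n_k / zf1
    f1_hz = -k_axis / (2.0 * np.pi * timing.C)
    f1_axis = p.carrier_ppm + f1_hz / p.larmor  # decreasing (k ascending)
    freqs = np.fft.fftshift(np.fft.fftfreq(zf2, d=dwell))
    f2_axis = p.carrier_ppm + freqs / p.larmor  # ascending -> flip below

    matrix = total[:, ::-1]
    f2_axis = f2_axis[::-1].copy()
    provenance = {
        "processing": config.to_dict(),
        "carrier_ppm": p.carrier_ppm,
        "larmor_MHz": p.larmor,
        "SW2_Hz": timing.SW2,
        "f1_span_Hz": timing.f1_span,
    }
    return Spectrum2D(
        matrix=matrix, f1_axis=f1_axis, f2_axis=f2_axis, provenance=provenance
    )


def calibrate(
    spec: Spectrum2D,
    measured: Sequence[Tuple[float, float]],
    references: Sequence[Tuple[float, float]],
) -> Spectrum2D:
    """Two-point chemical-shift calibration of both axes.

    ``measured`` are the observed (f1, f2) ppm positions of two reference
    peaks, ``references`` their true positions.  A per-axis affine map
    (scale, offset) is solved exactly from the two points and applied, so
    the reference peaks land exactly on their reference coordinates.
    """
    if len(measured) != 2 or len(references) != 2:
        raise ValueError("exactly two reference points are required")
    maps = []
    new_axes = []
    for axis_idx, axis in enumerate((spec.f1_axis, spec.f2_axis)):
        m1, m2 = measured[0][axis_idx], measured[1][axis_idx]
        r1, r2 = references[0][axis_idx], references[1][axis_idx]
        if m1 == m2:
            raise ValueError("coincident reference positions on one axis")
        scale = (r1 - r2) / (m1 - m2)
        offset = r1 - scale * m1
        maps.append({"scale": scale, "offset": offset})
        new_axes.append(scale * axis + offset)
    provenance = dict(spec.provenance)
    provenance["calibration"] = {"f1": maps[0], "f2": maps[1]}
    return Spectrum2D(
        matrix=spec.matrix,
        f1_axis=new_axes[0],
        f2_axis=new_axes[1],
        provenance=provenance,
    )


def find_peak(
    spec: Spectrum2D, f1: float, f2: float, window: float = 0.15
) -> Tuple[float, float]:
    """(f1, f2) ppm position of the intensity maximum near a target point.

    Searches a +/- ``window`` ppm box around (f1, f2).
    """
    m1 = np.abs(spec.f1_axis - f1) <= window
    m2 = np.abs(spec.f2_axis - f2) <= window
    if not (m1.any() and m2.any()):
        raise ValueError("search window falls outside the spectrum")
    sub = spec.matrix[np.ix_(m1, m2)]
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    return (
        float(spec.f1_axis[m1][i]),
        float(spec.f2_axis[m2][j]),
    )
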