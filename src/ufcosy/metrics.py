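"""Evaluation metrics: row-extracted SNR, peak volumes, CV, ghosts, detectability."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .recon import Spectrum2D

__all__ = [
    "Region",
    "PeakDef",
    "MetricsReport",
    "snr",
    "peak_volume",
    "relative_volumes",
    "cv",
    "predict_ghosts",
    "detectable_peaks",
    "read_peakdefs_tsv",
    "write_peakdefs_tsv",
]


@dataclass(frozen=True)
class Region:
    """Axis-aligned ppm rectangle; membership is half-open, [min, max)."""

    f1_min: float
    f1_max: float
    f2_min: float
    f2_max: float

    def __post_init__(self) -> None:
        if not (self.f1_min < self.f1_max and self.f2_min < self.f2_max):
            raise ValueError("region must satisfy min < max on both axes")

    def contains(self, f1, f2):
        return (
            (f1 >= self.f1_min) & (f1 < self.f1_max)
            & (f2 >= self.f2_min) & (f2 < self.f2_max)
        )


@dataclass(frozen=True)
class PeakDef:
    """A named peak region plus a signal-free noise region on the same row."""

    name: str
    peak_region: Region
    noise_region: Region

    def __post_init__(self) -> None:
        p, n = self.peak_region, self.noise_region
        overlap_f2 = p.f2_min < n.f2_max and n.f2_min < p.f2_max
        overlap_f1 = p.f1_min < n.f1_max and n.f1_min < p.f1_max
        if overlap_f1 and overlap_f2:
            raise ValueError("peak and noise regions must be disjoint")


@dataclass
class MetricsReport:
    snr: dict = field(default_factory=dict)
    volumes: dict = field(default_factory=dict)
    relative_volumes: dict = field(default_factory=dict)
    cv_percent: dict = field(default_factory=dict)
    ghosts: list = field(default_factory=list)
    detectable_count: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "snr": self.snr,
            "volumes": self.volumes,
            "relative_volumes": self.relative_volumes,
            "cv_percent": self.cv_percent,
            "ghosts": self.ghosts,
            "detectable_count": self.detectable_count,
        }


def _row_slice(spec: Spectrum2D, region: Region) -> np.ndarray:
    return region.contains(
        spec.f1_axis[:, None], spec.f2_axis[None, :]
    )


def snr(spec: Spectrum2D, pd_: PeakDef) -> float:
    """Row-extracted SNR of one peak.

    The f1 row passing through the in-region intensity maximum is extracted;
    SNR is the row maximum inside the peak region divided by the standard
    deviation over the noise region's f2 range on that same row.
    """
    peak_mask = _row_slice(spec, pd_.peak_region)
    if not peak_mask.any():
        raise ValueError(f"peak region of {pd_.name!r} is empty on this grid")
    masked = np.where(peak_mask, spec.matrix, -np.inf)
    row_idx, _ = np.unravel_index(np.argmax(masked), masked.shape)
    row = spec.matrix[row_idx]
    f2 = spec.f2_axis
    peak_cols = (f2 >= pd_.peak_region.f2_min) & (f2 < pd_.peak_region.f2_max)
    noise_cols = (f2 >= pd_.noise_region.f2_min) & (f2 < pd_.noise_region.f2_max)
    if not noise_cols.any():
        raise ValueError(f"noise region of {pd_.name!r} is empty on this grid")
    noise_std = float(np.std(row[noise_cols], ddof=1))
    if noise_std == 0.0:
        raise ValueError("zero noise standard deviation (noiseless input)")
    return float(np.max(row[peak_cols]) / noise_std)


def peak_volume(spec: Spectrum2D, region: Region) -> float:
    """Sum of matrix cells whose coordinates fall in the half-open region."""
    mask = _row_slice(spec, region)
    if not mask.any():
        raise ValueError("region contains no grid points")
    return float(spec.matrix[mask].sum())


def relative_volumes(volumes: dict, reference: str = "TSP") -> dict:
    """Volumes normalised by the reference peak's volume."""
    if reference not in volumes:
        raise KeyError(f"reference peak {reference!r} not in volume table")
    ref = volumes[reference]
    if ref <= 0:
        raise ValueError("reference volume must be positive")
    return {name: v / ref for name, v in volumes.items()}


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: 100 * sample standard deviation / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least two replicates")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    if np.ptp(values) == 0.0:  # identical replicates: exactly zero
        return 0.0
    return float(100.0 * values.std(ddof=1) / mean)


def predict_ghosts(
    parent_f2: float,
    SW2: float,
    N_i: int,
    larmor: float,
    interleave_factors: Sequence[float],
    carrier_ppm: float = 3.0,
) -> List[Tuple[float, complex]]:
    """Interleaving ghost positions and relative amplitudes of one parent peak.

    A per-interleave modulation of the merged conventional-time grid is
    periodic with period ``N_i``, so it convolves the parent line with the
    DFT of the factor sequence: ghost m (m = 1..N_i-1) appears at
    ``parent_f2 + m * SW2 / N_i`` (folded into the spectral window) with
    complex amplitude ``DFT(factors)[m] / DFT(factors)[0]`` relative to the
    parent.  Equal factors give zero ghosts.
    """
    if N_i < 1:
        raise ValueError("N_i must be >= 1")
    factors = np.asarray(interleave_factors, dtype=complex)
    if factors.shape != (N_i,):
        raise ValueError("interleave_factors must have length N_i")
    spectrum = np.fft.fft(factors)
    if spectrum[0] == 0:
        raise ValueError("mean interleave factor must be non-zero")
    ghosts = []
    parent_hz = (parent_f2 - carrier_ppm) * larmor
    for m in range(1, N_i):
        offset = parent_hz + m * SW2 / N_i
        folded = (offset + SW2 / 2.0) % SW2 - SW2 / 2.0
        ghost_ppm = carrier_ppm + folded / larmor
        ghosts.append((ghost_ppm, complex(spectrum[m] / spectrum[0])))
    return ghosts


def _noise_floor(spec: Spectrum2D) -> float:
    """Robust noise estimate: scaled median absolute deviation of the matrix.

    Peaks occupy a tiny fraction of the grid, so the MAD tracks the noise.
    """
    m = spec.matrix
    med = np.median(m)
    return float(1.4826 * np.median(np.abs(m - med)))


def detectable_peaks(
    spec: Spectrum2D,
    expected: Iterable[Tuple[float, float]],
    threshold: float = 5.0,
    ghost_positions: Optional[Iterable[Tuple[float, float]]] = None,
    linewidth: float = 0.05,
    search_window: float = 0.06,
    noise_std: Optional[float] = None,
) -> int:
    """Count expected peaks detectable above the noise and clear of ghosts.

    A peak counts when the local maximum within ``search_window`` ppm of its
    expected position reaches ``threshold`` times the noise level, and the
    position is not within ``linewidth`` ppm (both axes) of any predicted
    solvent ghost.  ``noise_std`` defaults to a robust MAD estimate over the
    whole matrix.
    """
    if noise_std is None:
        noise_std = _noise_floor(spec)
    ghost_positions = list(ghost_positions or [])
    f1a, f2a = spec.f1_axis, spec.f2_axis
    count = 0
    for f1, f2 in expected:
        if not (f1a.min() <= f1 <= f1a.max() and f2a.min() <= f2 <= f2a.max()):
            continue
        shadowed = any(
            abs(f1 - g1) <= linewidth and abs(f2 - g2) <= linewidth
            for g1, g2 in ghost_positions
        )
        if shadowed:
            continue
        m1 = np.abs(f1a - f1) <= search_window
        m2 = np.abs(f2a - f2) <= search_window
        if not (m1.any() and m2.any()):
            continue
        local_max = float(spec.matrix[np.ix_(m1, m2)].max())
        if noise_std == 0.0 or local_max / noise_std >= threshold:
            count += 1
    return count


_PEAKDEF_COLUMNS = [
    "name",
    "f1_min", "f1_max", "f2_min", "f2_max",
    "noise_f1_min", "noise_f1_max", "noise_f2_min", "noise_f2_max",
]


def read_peakdefs_tsv(path) -> List[PeakDef]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_PEAKDEF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    defs = []
    for _, r in df.iterrows():
        defs.append(PeakDef(
            name=str(r["name"]),
            peak_region=Region(
                r["f1_min"], r["f1_max"], r["f2_min"], r["f2_max"]
            ),
            noise_region=Region(
                r["noise_f1_min"], r["noise_f1_max"],
                r["noise_f2_min"], r["noise_f2_max"],
            ),
        ))
    return defs


def write_peakdefs_tsv(defs: Iterable[PeakDef], path) -> None:
    rows = []
    for d in defs:
        p, n = d.peak_region, d.noise_region
        rows.append({
            "name": d.name,
            "f1_min": p.f1_min, "f1_max": p.f1_max,
            "f2_min": p.f2_min, "f2_max": p.f2_max,
            "noise_f1_min": n.f1_min, "noise_f1_max": n.f1_max,
            "noise_f2_min": n.f2_min, "noise_f2_max": n.f2_max,
        })
    pd.DataFrame(rows, columns=_PEAKDEF_COLUMNS).to_csv(
        path, sep="\t", index=False
    )
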