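"""Spin-system mixtures and their expansion into 2D COSY peak lists.

This is a first-order (weak-coupling) peak-level representation: every site
contributes a diagonal multiplet and every scalar coupling a mirror-symmetric
pair of cross-peak multiplet blocks.  No density-matrix dynamics are modelled;
cross-peak amplitudes are phenomenological (see ``cross_transfer``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "Site",
    "Coupling",
    "SpinSystem",
    "Peak2D",
    "MixtureSpec",
    "expand_multiplet",
    "peaklist",
    "wine_fixture",
    "read_mixture_tsv",
    "write_mixture_tsv",
]

_TSV_COLUMNS = [
    "system", "site", "shift_ppm", "n_protons",
    "J_partner", "J_hz", "concentration", "class", "T2_s",
]


@dataclass(frozen=True)
class Site:
    """A chemically equivalent group of protons at one chemical shift."""

    shift: float          # ppm
    n_protons: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        if not math.isfinite(self.shift):
            raise ValueError("shift must be finite")


@dataclass(frozen=True)
class Coupling:
    """Scalar coupling between two sites of the same spin system."""

    site_a: str
    site_b: str
    J: float  # Hz

    def __post_init__(self) -> None:
        if self.J <= 0:
            raise ValueError("J must be positive")
        if self.site_a == self.site_b:
            raise ValueError("a site cannot couple to itself")


@dataclass
class SpinSystem:
    name: str
    sites: list = field(default_factory=list)
    couplings: list = field(default_factory=list)
    concentration: float = 1.0   # arbitrary amplitude units
    klass: str = "metabolite"    # one of {metabolite, solvent, reference}
    T2: float = 0.5              # s

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.T2 <= 0:
            raise ValueError("T2 must be positive")
        if self.klass not in ("metabolite", "solvent", "reference"):
            raise ValueError(f"unknown class {self.klass!r}")
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate site labels in system {self.name!r}")
        for c in self.couplings:
            if c.site_a not in labels or c.site_b not in labels:
                raise ValueError(
                    f"coupling references unknown site in system {self.name!r}"
                )

    def site(self, label: str) -> Site:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass(frozen=True)
class Peak2D:
    """One resolved line of the 2D peak list driving the simulator."""

    f1: float             # ppm
    f2: float             # ppm
    amplitude: float      # arbitrary units
    T2: float             # s
    kind: str             # {diagonal, cross}
    system: str
    klass: str = "metabolite"
    faraway: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.kind not in ("diagonal", "cross"):
            raise ValueError(f"unknown peak kind {self.kind!r}")


@dataclass
class MixtureSpec:
    """A mixture of spin systems plus solvent-behaviour knobs.

    ``faraway_water_fraction`` is the fraction of the water amplitude carried
    by nuclei at the edge of the RF coil; these see off-nominal RF, escape the
    frequency-selective suppression bands, and are only attenuated by the
    NOESY block.  ``cross_transfer`` scales cross-peak amplitudes relative to
    the geometric mean of the connected diagonal amplitudes.
    """

    systems: list = field(default_factory=list)
    faraway_water_fraction: float = 1e-3
    cross_transfer: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.faraway_water_fraction <= 0.1:
            raise ValueError("faraway_water_fraction must be in [0, 0.1]")
        if not 0.0 < self.cross_transfer <= 1.0:
            raise ValueError("cross_transfer must be in (0, 1]")

    def system(self, name: str) -> SpinSystem:
        for s in self.systems:
            if s.name == name:
                return s
        raise KeyError(name)


def expand_multiplet(
    site: Site, couplings: Iterable[tuple]
) -> list:
    """First-order multiplet of a site: list of ``(offset_hz, weight)``.

    Each coupling ``(J, n_partner)`` to ``n_partner`` equivalent protons
    splits every existing line into ``n_partner + 1`` lines with Pascal's
    triangle weights; the full pattern is the iterated binomial convolution.
    Weights sum to 1 and offsets are symmetric about 0.
    """
    lines = {0.0: 1.0}
    for J, n_partner in couplings:
        if J < 0:
            raise ValueError("J must be non-negative")
        if n_partner < 1:
            raise ValueError("n_partner must be >= 1")
        weights = [math.comb(n_partner, k) for k in range(n_partner + 1)]
        total = float(sum(weights))
        new_lines: dict = {}
        for offset, w in lines.items():
            for k, bw in enumerate(weights):
                o = offset + (k - n_partner / 2.0) * J
                o = round(o, 9)  # merge numerically coincident lines
                new_lines[o] = new_lines.get(o, 0.0) + w * bw / total
        lines = new_lines
    return sorted(lines.items())


def _site_couplings(system: SpinSystem, label: str) -> list:
    """Couplings of one site as ``(J, n_partner)`` tuples."""
    out = []
    for c in system.couplings:
        if c.site_a == label:
            out.append((c.J, system.site(c.site_b).n_protons))
        elif c.site_b == label:
            out.append((c.J, system.site(c.site_a).n_protons))
    return out


def peaklist(mix: MixtureSpec, larmor: float = 700.28) -> list:
    """Expand a mixture into the flat list of :class:`Peak2D` lines.

    Diagonal blocks carry total amplitude ``concentration * n_protons``
    spread over the 2D multiplet (outer product of the 1D multiplet with
    itself).  Each coupling contributes two mirror-image cross blocks of
    total amplitude ``cross_transfer * concentration * sqrt(n_a * n_b)``
    each, so the (f1,f2) and (f2,f1) blocks are exactly equal.  Water
    systems additionally emit a faraway-water diagonal line.

    ``larmor`` (MHz) converts multiplet splittings in Hz to ppm.
    """
    peaks: list = []
    for system in mix.systems:
        for site in system.sites:
            mult = expand_multiplet(site, _site_couplings(system, site.label))
            total = system.concentration * site.n_protons
            for o1, w1 in mult:
                for o2, w2 in mult:
                    amp = total * w1 * w2
                    if amp == 0.0:
                        continue
                    peaks.append(Peak2D(
                        f1=site.shift + o1 / larmor,
                        f2=site.shift + o2 / larmor,
                        amplitude=amp,
                        T2=system.T2,
                        kind="diagonal",
                        system=system.name,
                        klass=system.klass,
                    ))
        for c in system.couplings:
            sa, sb = system.site(c.site_a), system.site(c.site_b)
            amp_total = (
                mix.cross_transfer
                * system.concentration
                * math.sqrt(sa.n_protons * sb.n_protons)
            )
            mult_a = expand_multiplet(sa, _site_couplings(system, sa.label))
            mult_b = expand_multiplet(sb, _site_couplings(system, sb.label))
            for first, second in ((sa, sb), (sb, sa)):
                m1 = mult_a if first is sa else mult_b
                m2 = mult_b if first is sa else mult_a
                for o1, w1 in m1:
                    for o2, w2 in m2:
                        amp = amp_total * w1 * w2
                        if amp == 0.0:
                            continue
                        peaks.append(Peak2D(
                            f1=first.shift + o1 / larmor,
                            f2=second.shift + o2 / larmor,
                            amplitude=amp,
                            T2=system.T2,
                            kind="cross",
                            system=system.name,
                            klass=system.klass,
                        ))
        if system.name == "water" and mix.faraway_water_fraction > 0:
            site = system.sites[0]
            peaks.append(Peak2D(
                f1=site.shift,
                f2=site.shift,
                amplitude=(
                    mix.faraway_water_fraction
                    * system.concentration * site.n_protons
                ),
                T2=system.T2,
                kind="diagonal",
                system="water",
                klass="solvent",
                faraway=True,
            ))
    return peaks


def _singlet(name, shift, n, conc, klass="metabolite", T2=0.5, label="H"):
    return SpinSystem(
        name=name,
        sites=[Site(shift=shift, n_protons=n, label=label)],
        concentration=conc,
        klass=klass,
        T2=T2,
    )


def _coupled(name, sites, couplings, conc, klass="metabolite", T2=0.5):
    return SpinSystem(
        name=name,
        sites=[Site(shift=s, n_protons=n, label=lbl) for lbl, s, n in sites],
        couplings=[Coupling(a, b, J) for a, b, J in couplings],
        concentration=conc,
        klass=klass,
        T2=T2,
    )


def wine_fixture() -> MixtureSpec:
    """A wine-like test mixture dominated by water and ethanol.

    Water and ethanol amplitudes exceed every metabolite by more than three
    orders of magnitude.  TSP sits exactly at 0.00 ppm and tartrate exactly
    at 4.47 ppm so the pair can anchor two-point chemical-shift calibration.
    Metabolite shifts not otherwise fixed are illustrative literature-style
    values, not measured ones.
    """
    systems = [
        _singlet("water", 4.79, 2, 5e4, klass="solvent", T2=0.3),
        _coupled(
            "ethanol",
            [("CH3", 1.18, 3), ("CH2", 3.65, 2)],
            [("CH3", "CH2", 7.0)],
            3.3e3, klass="solvent", T2=0.6,
        ),
        _singlet("TSP", 0.00, 9, 5.0, klass="reference", T2=0.8),
        _singlet("tartrate", 4.47, 2, 40.0),
        _coupled(
            "lactate",
            [("CH3", 1.33, 3), ("CH", 4.11, 1)],
            [("CH3", "CH", 6.9)],
            30.0,
        ),
        _singlet("acetate", 1.91, 3, 30.0),
        _singlet("succinate", 2.51, 4, 25.0),
        _coupled(
            "alanine",
            [("CH3", 1.48, 3), ("CH", 3.78, 1)],
            [("CH3", "CH", 7.2)],
            3.0,
        ),
        _coupled(
            "isopentanol",
            [("CH3", 0.90, 6), ("CH2", 1.45, 2), ("OCH2", 3.61, 2)],
            [("CH3", "CH2", 6.6), ("CH2", "OCH2", 6.9)],
            8.0,
        ),
        _coupled(
            "isobutanol",
            [("CH3", 0.88, 6), ("CH2", 3.35, 2)],
            [("CH3", "CH2", 6.7)],
            7.0,
        ),
        _coupled(
            "acetoin",
            [("CH3", 1.37, 3), ("CH", 4.41, 1)],
            [("CH3", "CH", 7.1)],
            2.0,
        ),
        _coupled(
            "13-propanediol",
            [("CH2", 1.78, 2), ("OCH2", 3.67, 4)],
            [("CH2", "OCH2", 6.4)],
            6.0,
        ),
        _coupled(
            "myo-inositol",
            [("H2", 4.05, 1), ("H13", 3.52, 2)],
            [("H2", "H13", 2.8)],
            2.5,
        ),
        _coupled(
            "23-butanediol",
            [("CH3", 1.14, 6), ("CH", 3.73, 2)],
            [("CH3", "CH", 6.3)],
            2.5,
        ),
        _coupled(
            "ethyl-acetate",
            [("CH3", 1.26, 3), ("OCH2", 4.12, 2)],
            [("CH3", "OCH2", 7.1)],
            4.0,
        ),
        _coupled(
            "proline",
            [("Hg", 2.00, 2), ("Hd", 3.38, 2)],
            [("Hg", "Hd", 6.8)],
            1.2,
        ),
        _singlet("methanol", 3.34, 3, 6.0),
        _singlet("choline", 3.19, 9, 3.0),
        _coupled(
            "glycerol",
            [("CH", 3.78, 1), ("CH2", 3.56, 4)],
            [("CH", "CH2", 6.0)],
            8.0,
        ),
        _coupled(
            "ethanolamine",
            [("NCH2", 3.14, 2), ("OCH2", 3.82, 2)],
            [("NCH2", "OCH2", 5.2)],
            1.5,
        ),
    ]
    return MixtureSpec(systems=systems)


def write_mixture_tsv(mix: MixtureSpec, path) -> None:
    """Serialise a mixture to the tabular TSV interchange format.

    One row per (site, coupling) pair; sites without couplings get a single
    row with empty J columns.  System-level fields are repeated on each row.
    """
    rows = []
    for system in mix.systems:
        for site in system.sites:
            cps = [
                (c.site_b if c.site_a == site.label else c.site_a, c.J)
                for c in system.couplings
                if site.label in (c.site_a, c.site_b)
            ]
            if not cps:
                cps = [("", float("nan"))]
            for partner, J in cps:
                rows.append({
                    "system": system.name,
                    "site": site.label,
                    "shift_ppm": site.shift,
                    "n_protons": site.n_protons,
                    "J_partner": partner,
                    "J_hz": J,
                    "concentration": system.concentration,
                    "class": system.klass,
                    "T2_s": system.T2,
                })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mixture_tsv(
    path,
    faraway_water_fraction: float = 1e-3,
    cross_transfer: float = 0.3,
) -> MixtureSpec:
    """Load a mixture from the TSV interchange format."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mixture table missing columns: {sorted(missing)}")
    systems = []
    for name, g in df.groupby("system", sort=False):
        sites = []
        for lbl, gs in g.groupby("site", sort=False):
            row = gs.iloc[0]
            sites.append(Site(
                shift=float(row["shift_ppm"]),
                n_protons=int(row["n_protons"]),
                label=str(lbl),
            ))
        seen = set()
        couplings = []
        for _, row in g.iterrows():
            partner = row["J_partner"]
            if pd.isna(partner) or partner == "":
                continue
            key = frozenset((str(row["site"]), str(partner)))
            if key in seen:
                continue
            seen.add(key)
            couplings.append(
                Coupling(str(row["site"]), str(partner), float(row["J_hz"]))
            )
        row0 = g.iloc[0]
        systems.append(SpinSystem(
            name=str(name),
            sites=sites,
            couplings=couplings,
            concentration=float(row0["concentration"]),
            klass=str(row0["class"]),
            T2=float(row0["T2_s"]),
        ))
    return MixtureSpec(
        systems=systems,
        faraway_water_fraction=faraway_water_fraction,
        cross_transfer=cross_transfer,
    )
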