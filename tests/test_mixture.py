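import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ufcosy.mixture import (
    Coupling,
    MixtureSpec,
    Site,
    SpinSystem,
    expand_multiplet,
    peaklist,
    read_mixture_tsv,
    wine_fixture,
    write_mixture_tsv,
)


def brute_force_multiplet(couplings):
    """Independent oracle: enumerate every partner spin-1/2 configuration."""
    from itertools import product

    n_total = sum(n for _, n in couplings)
    lines: dict = {}
    spin_sets = [product((-1, 1), repeat=n) for _, n in couplings]
    for states in product(*[list(s) for s in spin_sets]):
        # J * (integer spin sum) / 2 is computed the same way every time,
        # so equal offsets merge exactly
        off = round(
            sum(J * sum(s) / 2.0 for (J, _), s in zip(couplings, states)), 9
        )
        lines[off] = lines.get(off, 0.0) + 1.0 / 2 ** n_total
    return sorted(lines.items())


class TestExpandMultiplet:
    def test_singlet_identity(self):
        assert expand_multiplet(Site(shift=1.0), []) == [(0.0, 1.0)]

    def test_quartet(self):
        lines = expand_multiplet(Site(shift=1.0), [(7.0, 3)])
        offsets = [o for o, _ in lines]
        weights = [w for _, w in lines]
        assert offsets == pytest.approx([-10.5, -3.5, 3.5, 10.5])
        assert weights == pytest.approx([1 / 8, 3 / 8, 3 / 8, 1 / 8])

    def test_doublet_of_doublets(self):
        lines = expand_multiplet(Site(shift=1.0), [(10.0, 1), (4.0, 1)])
        assert len(lines) == 4
        assert [w for _, w in lines] == pytest.approx([0.25] * 4)
        assert lines == pytest.approx(brute_force_multiplet([(10.0, 1), (4.0, 1)]))

    def test_negative_j_rejected(self):
        with pytest.raises(ValueError):
            expand_multiplet(Site(shift=1.0), [(-1.0, 2)])

    @given(st.lists(
        # dyadic J values make the oracle's float sums exact
        st.tuples(
            st.integers(1, 40).map(lambda k: k / 2.0), st.integers(1, 4)
        ),
        max_size=3,
    ))
    @settings(max_examples=60, deadline=None)
    def test_weights_sum_to_one_and_symmetric(self, couplings):
        lines = expand_multiplet(Site(shift=0.0), couplings)
        weights = [w for _, w in lines]
        offsets = [o for o, _ in lines]
        assert sum(weights) == pytest.approx(1.0)
        assert sorted(offsets) == pytest.approx(sorted(-o for o in offsets))
        assert lines == pytest.approx(brute_force_multiplet(couplings))


def ethanol_system(concentration=1.0):
    return SpinSystem(
        name="ethanol",
        sites=[
            Site(shift=1.18, n_protons=3, label="CH3"),
            Site(shift=3.65, n_protons=2, label="CH2"),
        ],
        couplings=[Coupling("CH3", "CH2", 7.0)],
        concentration=concentration,
        klass="solvent",
    )


class TestPeaklist:
    def test_single_singlet_system(self):
        mix = MixtureSpec(systems=[
            SpinSystem(name="x", sites=[Site(shift=2.0, label="H")]),
        ])
        peaks = peaklist(mix)
        assert len(peaks) == 1
        assert peaks[0].kind == "diagonal"
        assert peaks[0].amplitude == pytest.approx(1.0)

    def test_empty_mixture(self):
        assert peaklist(MixtureSpec(systems=[])) == []

    def test_ethanol_blocks_and_mirror_symmetry(self):
        mix = MixtureSpec(systems=[ethanol_system()], faraway_water_fraction=0)
        peaks = peaklist(mix)
        diag = [p for p in peaks if p.kind == "diagonal"]
        cross = [p for p in peaks if p.kind == "cross"]
        # CH3 triplet: 3 lines -> 9 diag lines; CH2 quartet: 4 -> 16
        assert len(diag) == 9 + 16
        # two mirror blocks of 3*4 lines each
        assert len(cross) == 2 * 12
        amp = {(round(p.f1, 6), round(p.f2, 6)): p.amplitude for p in cross}
        for (f1, f2), a in amp.items():
            assert amp[(f2, f1)] == pytest.approx(a)

    def test_diagonal_amplitude_totals(self):
        mix = MixtureSpec(systems=[ethanol_system(2.0)], faraway_water_fraction=0)
        diag = [p for p in peaklist(mix) if p.kind == "diagonal"]
        total = sum(p.amplitude for p in diag)
        # concentration * (3 + 2) protons
        assert total == pytest.approx(2.0 * 5)

    def test_wine_fixture_count_matches_enumeration_oracle(self, wine):
        larmor = 700.28

        def n_lines(system, site):
            cps = [
                (c.J, system.site(c.site_b if c.site_a == site.label
                                  else c.site_a).n_protons)
                for c in system.couplings
                if site.label in (c.site_a, c.site_b)
            ]
            return len(brute_force_multiplet(cps))

        expected = 0
        for system in wine.systems:
            for site in system.sites:
                expected += n_lines(system, site) ** 2
            for c in system.couplings:
                la = n_lines(system, system.site(c.site_a))
                lb = n_lines(system, system.site(c.site_b))
                expected += 2 * la * lb
            if system.name == "water" and wine.faraway_water_fraction > 0:
                expected += 1
        assert len(peaklist(wine, larmor)) == expected

    def test_linearity_in_concentration(self, wine):
        alpha = 3.7
        scaled = MixtureSpec(
            systems=[
                replace(s, concentration=s.concentration * alpha)
                if s.name == "lactate" else s
                for s in wine.systems
            ],
            faraway_water_fraction=wine.faraway_water_fraction,
            cross_transfer=wine.cross_transfer,
        )
        base = {(p.system, p.f1, p.f2, p.kind, p.faraway): p.amplitude
                for p in peaklist(wine)}
        for p in peaklist(scaled):
            ref = base[(p.system, p.f1, p.f2, p.kind, p.faraway)]
            factor = alpha if p.system == "lactate" else 1.0
            assert p.amplitude == pytest.approx(ref * factor, rel=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_mirror_symmetry_random_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        sites = [
            Site(shift=float(rng.uniform(0, 6)), n_protons=int(rng.integers(1, 4)),
                 label=f"s{i}")
            for i in range(3)
        ]
        couplings = [
            Coupling("s0", "s1", float(rng.uniform(2, 12))),
            Coupling("s1", "s2", float(rng.uniform(2, 12))),
        ]
        mix = MixtureSpec(systems=[SpinSystem(
            name="rand", sites=sites, couplings=couplings,
            concentration=float(rng.uniform(0.1, 10)),
        )])
        cross = [p for p in peaklist(mix) if p.kind == "cross"]
        amp: dict = {}
        for p in cross:
            amp[(round(p.f1, 6), round(p.f2, 6))] = (
                amp.get((round(p.f1, 6), round(p.f2, 6)), 0.0) + p.amplitude
            )
        for (f1, f2), a in amp.items():
            assert amp[(f2, f1)] == pytest.approx(a, rel=1e-9)


class TestWineFixture:
    def test_reference_at_zero_ppm(self, wine):
        shifts = [s.shift for sys in wine.systems for s in sys.sites
                  if sys.klass == "reference"]
        assert 0.00 in shifts

    def test_tartrate_at_4_47_ppm(self, wine):
        shifts = [s.shift for sys in wine.systems for s in sys.sites]
        assert 4.47 in shifts

    def test_solvent_dominance(self, wine):
        peaks = peaklist(wine)
        solvent = max(p.amplitude for p in peaks if p.klass == "solvent")
        metabolite = max(p.amplitude for p in peaks
                         if p.klass in ("metabolite", "reference"))
        assert solvent / metabolite >= 1e3

    def test_size_and_required_systems(self, wine):
        names = {s.name for s in wine.systems}
        assert 15 <= len(wine.systems) <= 25
        for required in ("water", "ethanol", "TSP", "tartrate", "lactate",
                         "acetate", "succinate", "isopentanol", "isobutanol",
                         "acetoin", "13-propanediol", "myo-inositol"):
            assert required in names

    def test_shift_window(self, wine):
        for system in wine.systems:
            for site in system.sites:
                if system.name != "water":
                    assert 0.0 <= site.shift <= 6.0


class TestTsvRoundTrip:
    def test_round_trip(self, wine, tmp_path):
        path = tmp_path / "mix.tsv"
        write_mixture_tsv(wine, path)
        back = read_mixture_tsv(path)
        assert len(back.systems) == len(wine.systems)
        base = {
            (p.system, round(p.f1, 9), round(p.f2, 9), p.kind, p.faraway):
            p.amplitude
            for p in peaklist(wine)
        }
        for p in peaklist(back):
            key = (p.system, round(p.f1, 9), round(p.f2, 9), p.kind, p.faraway)
            assert base[key] == pytest.approx(p.amplitude)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("system\tsite\nfoo\tbar\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_mixture_tsv(path)

    def test_packaged_fixture_loads(self):
        from importlib.resources import files

        path = files("ufcosy").joinpath("data/wine_fixture.tsv")
        mix = read_mixture_tsv(str(path))
        assert {s.name for s in mix.systems} == {
            s.name for s in wine_fixture().systems
        }


class TestValidation:
    def test_bad_coupling(self):
        with pytest.raises(ValueError):
            Coupling("a", "a", 7.0)
        with pytest.raises(ValueError):
            Coupling("a", "b", -1.0)

    def test_bad_faraway_fraction(self):
        with pytest.raises(ValueError):
            MixtureSpec(systems=[], faraway_water_fraction=0.5)

    def test_unknown_site_in_coupling(self):
        with pytest.raises(ValueError, match="unknown site"):
            SpinSystem(
                name="x",
                sites=[Site(shift=1.0, label="a")],
                couplings=[Coupling("a", "b", 5.0)],
            )
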