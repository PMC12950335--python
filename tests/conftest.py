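import numpy as np
import pytest

from ufcosy.mixture import MixtureSpec, Peak2D, SpinSystem, Site, wine_fixture
from ufcosy.recon import ProcessingConfig, process, split_and_merge
from ufcosy.sequence import SequenceParams, derive_geometry
from ufcosy.simulate import average_scans, simulate_raw


@pytest.fixture(scope="session")
def wine():
    return wine_fixture()


@pytest.fixture
def default_params():
    return SequenceParams(N_s=1)


@pytest.fixture
def small_params():
    """Reduced grid for fast simulation-heavy tests."""
    return SequenceParams(N_acq=16, N_i=4, N_s=1, N_k=32)


def single_peak(f1, f2, amplitude=1.0, T2=0.5, klass="metabolite"):
    return Peak2D(
        f1=f1, f2=f2, amplitude=amplitude, T2=T2,
        kind="diagonal", system="test", klass=klass,
    )


def simulate_spectrum(peaks, params, config=None, seed=0, **kwargs):
    """Simulate -> average -> reconstruct in one call (noiseless by default)."""
    timing = derive_geometry(params)
    raw = simulate_raw(peaks, params, timing, seed=seed, **kwargs)
    return process(split_and_merge(average_scans(raw)), config, timing)


@pytest.fixture
def tiny_mixture():
    return MixtureSpec(systems=[
        SpinSystem(
            name="water",
            sites=[Site(shift=4.79, n_protons=2, label="H")],
            concentration=1e4,
            klass="solvent",
            T2=0.3,
        ),
        SpinSystem(
            name="probe",
            sites=[Site(shift=1.5, n_protons=1, label="H")],
            concentration=10.0,
        ),
    ])
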