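import pytest

from xciskew import build_reference_model
from xciskew.simulate import SimulationSpec, simulate_reference_cohort


@pytest.fixture(scope="session")
def ref_setup():
    """A default-conditions reference cohort with its fitted model.

    135 samples x 150 shared sites, population mixture of XCI ratios
    (90% random, 10% skewed), one fixed seed for the whole session.
    """
    spec = SimulationSpec(n_samples=135, n_sites=150, seed=11)
    cohort, truth, site_map = simulate_reference_cohort(spec)
    model = build_reference_model(cohort, seed=7)
    return spec, cohort, truth, site_map, model


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 30-sample x 40-site cohort for cheaper unit tests."""
    spec = SimulationSpec(n_samples=30, n_sites=40, seed=5)
    cohort, truth, site_map = simulate_reference_cohort(spec)
    return spec, cohort, truth, site_map
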