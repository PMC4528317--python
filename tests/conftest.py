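import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import poolwgr as pw

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_nam() -> pw.MarkerData:
    """Small NAM-like data set shared across tests: 6 RIL families x 30 lines."""
    return pw.simulate_nam_like(
        n_populations=6, lines_per_population=30, n_markers=60, n_chromosomes=3, seed=101
    )


@pytest.fixture(scope="session")
def small_trait(small_nam):
    """One simulated trait (rSD=1) on the shared small data set."""
    reduced, trait, arch = pw.simulate_trait(small_nam, n_qtl=8, rsd=1.0, seed=202)
    return reduced, trait, arch


@pytest.fixture(scope="session")
def tiny_fit(small_nam, small_trait):
    """A fitted BayesA + multilevel pair on the shared small data (short chains)."""
    reduced, trait, _ = small_trait
    y, _ = pw.standardize_phenotypes(trait.phenotypes)
    Z = pw.center_genotypes(reduced)
    st = pw.ChainSettings(200, 500, 2, seed=7)
    bayesa = pw.fit_bayesa(y, Z, st)
    multilevel = pw.fit_multilevel(y, Z, small_nam.population_labels, st)
    return Z, y, bayesa, multilevel


def two_marker_map(distance_cm: float) -> pw.GeneticMap:
    return pw.GeneticMap(
        np.array(["A", "B"], dtype=object),
        np.array([1, 1]),
        np.array([0.0, distance_cm]),
    )
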