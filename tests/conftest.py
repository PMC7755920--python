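import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promarch.clustering import cluster_ctss, subtract_ctss
from promarch.io import CtssDataset
from promarch.normalization import normalize_power_law
from promarch.synthetic import default_specs, simulate_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study():
    """The standard synthetic two-condition study, processed to tag clusters.

    500 sharp W-box promoters (WT-specific, sd 1), 500 broad promoters
    (mutant-dominated, sd 25), 100 shifting promoters; 10^6 tags per
    condition.
    """
    genome, truth, datasets = simulate_study(seed=STUDY_SEED)
    dep = subtract_ctss(datasets["wt"], datasets["mutant"])
    dep.sample_id = "dependent"
    indep = CtssDataset(datasets["mutant"].df.copy(), sample_id="independent")
    dep_n, _ = normalize_power_law(dep)
    indep_n, _ = normalize_power_law(indep)
    clusters = {
        "dependent": cluster_ctss(dep_n),
        "independent": cluster_ctss(indep_n),
    }
    return {
        "genome": genome,
        "truth": truth,
        "datasets": datasets,
        "dependent": dep_n,
        "independent": indep_n,
        "clusters": clusters,
    }


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for end-to-end pipeline tests."""
    specs = default_specs(n_sharp=100, n_broad=100, n_shifting=20)
    return simulate_study(seed=5, specs=specs, n_chroms=1, chrom_length=300_000,
                          total_tags=200_000, min_spacing=1000)
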