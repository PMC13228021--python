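import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strainvar.model import GenomeLayout
from strainvar.simulate import SimulationConfig, StrainSpec, simulate_strain

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def layout() -> GenomeLayout:
    return GenomeLayout.yeast_scaled()


@pytest.fixture(scope="session")
def sim_config(layout) -> SimulationConfig:
    return SimulationConfig(layout=layout)


@pytest.fixture(scope="session")
def diploid_sim(sim_config):
    """One diploid strain with an LOH tract of each class, a trisomy and a
    terminal duplication — shared read-only across tests."""
    spec = StrainSpec(
        name="dip",
        ploidy=2,
        aneuploidies=(("chrII", 1),),
        loh_tracts=(
            ("chrIV", 40000, 60000, "interstitial"),
            ("chrV", 37687, 57687, "terminal"),
            ("chrIX", 0, 43989, "upd"),
        ),
        cnvs=(("chrX", 0, 8000, 1),),
        n_hgt_genes=5,
        hgt_identity=0.80,
        n_indels=50,
    )
    return simulate_strain(sim_config, spec, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
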