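import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from braincoex import CoexpressionMatrix
from braincoex.simulate import (
    LdBlock,
    PlantedModule,
    SimulationConfig,
    default_config,
    make_gene_models,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Two planted modules over two regions; quick to simulate."""
    regions = (("cortex", 0.5), ("cerebellum", 0.5))
    mods = (
        PlantedModule(tuple(range(0, 20)), {"cortex": 1.5, "cerebellum": 0.0}, 0.9),
        PlantedModule(tuple(range(20, 40)), {"cortex": 0.0, "cerebellum": 1.5}, 0.9),
    )
    return SimulationConfig(
        seed=7,
        n_genes=60,
        n_donors=3,
        n_samples_per_donor=120,
        region_labels=regions,
        planted_modules=mods,
    )


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return default_config(seed=11)


@pytest.fixture()
def toy_coexpr() -> CoexpressionMatrix:
    """5-gene matrix with one strong pair and assorted weaker links."""
    genes = ["g1", "g2", "g3", "g4", "g5"]
    V = np.array(
        [
            [1.00, 0.90, 0.61, 0.60, -0.80],
            [0.90, 1.00, 0.10, 0.05, -0.10],
            [0.61, 0.10, 1.00, 0.70, 0.00],
            [0.60, 0.05, 0.70, 1.00, 0.20],
            [-0.80, -0.10, 0.00, 0.20, 1.00],
        ]
    )
    return CoexpressionMatrix(genes, V)


@pytest.fixture(scope="session")
def assoc_setup():
    """21 small genes on one chromosome with mixed LD blocks."""
    gm = make_gene_models(21, n_chromosomes=1)
    blocks, tot, i = [], 0, 0
    sizes, rs = [5, 3, 2], [0.6, 0.3, 0.0]
    n_snps = 200
    while tot < n_snps:
        s = min(sizes[i % 3], n_snps - tot)
        blocks.append(LdBlock(s, rs[i % 3] if s > 1 else 0.0))
        tot += s
        i += 1
    return gm, tuple(blocks), n_snps
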