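import numpy as np
import pytest

from parscope.homology import AlignerParams
from parscope.parcall import Thresholds
from parscope.simulate import (
    AmpliconFamily,
    SimulationConfig,
    XdegSegment,
    simulate_sex_chromosome_pair,
)


def small_config(seed: int = 0) -> SimulationConfig:
    """A fast desk-scale configuration: 300 kb X with a 100 kb PAR."""
    return SimulationConfig(
        x_length=300_000,
        par_length=100_000,
        xdeg_segments=[
            XdegSegment(30_000, (0.06, 0.38), 3),
            XdegSegment(15_000, (0.06, 0.38), 2),
        ],
        ampliconic_families=[
            AmpliconFamily(3, 1_500, (0.09, 0.26), "OBP"),
            AmpliconFamily(4, 1_500, (0.09, 0.26), "BDA20"),
        ],
        gene_length=1_500,
        n_gap_runs=[(30_000, 2_000), (60_000, 1_000)],
        marker_count=20,
        corruption_ops=[("fragment", "Y", (80_000, 180_000)), ("invert", "Y.2")],
        xdeg_x_buffer=30_000,
        seed=seed,
    )


def small_thresholds() -> Thresholds:
    return Thresholds(window=20_000, refine_schedule=(5_000, 1_000))


@pytest.fixture(scope="session")
def small_sim():
    return simulate_sex_chromosome_pair(small_config(seed=0))


@pytest.fixture(scope="session")
def aligner_params():
    return AlignerParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
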