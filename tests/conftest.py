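import logging

import numpy as np
import pytest

from medipkit import SimConfig, build_methylome, simulate_genome


@pytest.fixture(autouse=True)
def _quiet_clip_warnings(caplog):
    """Boundary-clip warnings are expected in many tests; keep logs quiet."""
    logging.getLogger("medipkit").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def small_sim():
    """One shared 50 kb simulation: genome, methylome, truth."""
    cfg = SimConfig(seed=11)
    genome = simulate_genome(cfg)
    methylome, truth = build_methylome(genome, cfg)
    return cfg, genome, methylome, truth


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
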