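import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    """8x10 matrix with additive structure plus noise, labelled like a screen."""
    rows = [f"BAIT{i:02d}" for i in range(8)]
    cols = [f"PREY{j:02d}" for j in range(10)]
    values = (
        0.3
        + rng.normal(0, 0.1, size=8)[:, None]
        + rng.normal(0, 0.1, size=10)[None, :]
        + rng.normal(0, 0.02, size=(8, 10))
    )
    return pd.DataFrame(values, index=rows, columns=cols)


@pytest.fixture(scope="session")
def simulated_screen():
    """Default desk-scale screen (50x50, 30 planted symmetric pairs, seed 1)."""
    from ecia import SimulationConfig, simulate_screen

    config = SimulationConfig(seed=1, include_controls=False)
    records, truth = simulate_screen(config)
    return config, records, truth


@pytest.fixture(scope="session")
def screen_pipeline_result(simulated_screen):
    """Residuals/scores/hits of the default simulated screen."""
    from ecia import assemble_matrix, call_hits, median_polish, score_residuals

    _, records, truth = simulated_screen
    matrix = assemble_matrix(records)
    decomp = median_polish(matrix)
    scores = score_residuals(decomp.residuals)
    hits = call_hits(scores)
    return {
        "matrix": matrix,
        "decomp": decomp,
        "scores": scores,
        "hits": hits,
        "truth": truth,
    }
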