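import numpy as np
import pytest

from synconsol import generate_patterns, imprint_patterns


@pytest.fixture(scope="session")
def small_patterns():
    """60 neurons, 6 dense patterns: stable under one-shot imprinting."""
    return generate_patterns(N=60, M=6, f=0.5, seed=3)


@pytest.fixture(scope="session")
def imprinted_z2(small_patterns):
    return imprint_patterns(small_patterns, z=2)


@pytest.fixture(scope="session")
def consolidated_z2(small_patterns, imprinted_z2):
    from synconsol import ConsolidationConfig, consolidate

    cfg = ConsolidationConfig(cycles=2500, eta=0.005, beta_growth=1.002)
    state, diag = consolidate(imprinted_z2, small_patterns, cfg)
    return state, diag


@pytest.fixture(scope="session")
def power_law_table():
    """Exact |dw| = 0.3 * w**0.7 fixture with alternating branch signs."""
    import pandas as pd

    from synconsol.synapse_sim import TrajectoryTable

    rng = np.random.default_rng(42)
    n = 400
    w0 = np.maximum(rng.lognormal(-1.0, 0.8, size=n), 0.05)  # keep w1 > 0 exactly
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    w1 = w0 + sign * 0.3 * w0**0.7
    df = pd.DataFrame(
        {
            "synapse_id": np.tile(np.arange(n), 2),
            "time": np.repeat([0.0, 0.5], n),
            "strength": np.concatenate([w0, w1]),
        }
    )
    return TrajectoryTable(df=df, meta={"constructed": True})
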