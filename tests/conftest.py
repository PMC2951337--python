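import numpy as np
import pandas as pd
import pytest

from lumisig.synthdata import KnockdownSimSpec, simulate_knockdown


@pytest.fixture(scope="session")
def knockdown_small():
    """300-gene 5v6 knockdown experiment with 10% planted DE."""
    spec = KnockdownSimSpec(n_genes=300, de_fraction=0.1, effect_size=2.0,
                            sigma=0.5, seed=11)
    return simulate_knockdown(spec)


@pytest.fixture(scope="session")
def toy_signature():
    rng = np.random.default_rng(7)
    w = pd.Series(rng.normal(size=40), index=[f"SG{i:04d}" for i in range(40)])
    return w[w != 0]
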