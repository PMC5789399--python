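import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_rm_table(rng, n=6, a=3, b=4, effect=0.0):
    """Random fully crossed long table with an optional condition effect."""
    rows = []
    offsets = rng.normal(0, 1, n)
    for s in range(n):
        for i in range(a):
            for j in range(b):
                val = offsets[s] + effect * i + rng.normal(0, 1)
                rows.append((f"s{s:02d}", f"c{i}", float(j), val))
    return pd.DataFrame(rows, columns=["subject", "condition", "time_min", "gamma_deg"])


@pytest.fixture
def rm_table(rng):
    return make_rm_table(rng, effect=0.8)
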