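import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from relapsekit.containers import FeatureTable, NOMINAL, NUMERIC

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def make_table(n=20, seed=0, informative=True):
    """Small labeled mixed-type table: one informative nominal + numerics."""
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2 + 1)[:n]
    nom = np.where(y == 1,
                   rng.choice(["a", "b"], size=n, p=[0.9, 0.1]),
                   rng.choice(["a", "b"], size=n, p=[0.1, 0.9]))
    num = rng.normal(y * (2.0 if informative else 0.0), 1.0)
    noise = rng.normal(size=n)
    df = pd.DataFrame({"habit": nom, "marker": num, "noise": noise},
                      index=[f"P{i}" for i in range(n)])
    kinds = {"habit": NOMINAL, "marker": NUMERIC, "noise": NUMERIC}
    return FeatureTable(df, kinds, label=pd.Series(y, index=df.index))


@pytest.fixture
def small_table():
    return make_table()
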