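import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import panicle as pn

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_counts():
    """3 DP vs 3 SP count matrix with condition labels."""
    rng = np.random.default_rng(11)
    df = pd.DataFrame(rng.poisson(50.0, size=(20, 6)),
                      index=[f"g{i}" for i in range(20)],
                      columns=["DP1", "DP2", "DP3", "SP1", "SP2", "SP3"])
    cond = {s: s[:2] for s in df.columns}
    return pn.ExpressionMatrix(values=df, value_kind="counts", condition=cond)


def two_lv_data(n=200, beta=0.5, seed=0):
    """Single-indicator two-block dataset with a known path coefficient."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = beta * x + np.sqrt(1 - beta ** 2) * rng.standard_normal(n)
    data = pn.PlsSemData(case_ids=[f"c{i}" for i in range(n)],
                         indicator_ids=["a1", "b1"], X=np.column_stack([x, y]))
    blocks = [pn.BlockSpec("A", ("a1",)), pn.BlockSpec("B", ("b1",))]
    inner = pn.InnerModel(("A", "B"), (("A", "B"),))
    return data, blocks, inner


@pytest.fixture
def ctk_model():
    """Built-in CTK structure with its reported coefficients as truth
    (direct hormone->flowering edge generated with coefficient 0)."""
    spec = pn.builtin_model("CTK")
    inner = spec.inner_model()
    b_true = dict(spec.reported_paths)
    b_true[("CTK", "flowering")] = 0.0
    loadings = {lv: (1.0,) for lv in inner.lv_names}
    blocks = [pn.BlockSpec(lv, (f"{lv}_x1",)) for lv in inner.lv_names]
    return spec, inner, b_true, loadings, blocks
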