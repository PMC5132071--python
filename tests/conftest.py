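import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tolsig import CohortConfig, encode_drug_design, simulate_cohort, simulate_expression

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact confounded cohort shared by read-only tests."""
    cfg = CohortConfig(n_tolerant=14, n_stable=80, n_chronic=16, n_healthy=8,
                       n_genes=40, overlap_mode="forced-overlap", seed=7)
    meta, design = simulate_cohort(cfg)
    expr, truth = simulate_expression(meta, design, cfg)
    treated_design, _ = encode_drug_design(meta)
    return {"config": cfg, "meta": meta, "design": design,
            "treated_design": treated_design, "expr": expr, "truth": truth}


@pytest.fixture
def labels_for(small_cohort):
    meta = small_cohort["meta"].set_index("sample_id")

    def _labels(expr):
        ids = [s for s in expr.columns if meta.loc[s, "group"] != "healthy"]
        return pd.Series((meta.loc[ids, "group"] == "tolerant").astype(int).to_numpy(),
                         index=ids)

    return _labels
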