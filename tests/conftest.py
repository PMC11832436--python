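import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fgf21cohort.simulate import SimConfig, generate_cohort

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def strong_cohort():
    """Full-size cohort (66 controls, 117/159/120 patients) in the
    strong-effects regime where planted strata are essentially separable."""
    config = SimConfig(seed=7).with_strong_effects()
    expression, meta, truth = generate_cohort(config)
    return config, expression, meta, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for fast differential-expression tests."""
    config = SimConfig(
        seed=11, n_controls=20, n_up=15, n_down=15, n_unchanged=10,
        n_genes=300, noise_sd=0.3,
    ).with_strong_effects()
    expression, meta, truth = generate_cohort(config)
    return config, expression, meta, truth


@pytest.fixture()
def tiny_expression():
    """Hand-sized matrix: 3 genes x (2 controls + 3 patients)."""
    expr = pd.DataFrame(
        {
            "C1": [10.0, 4.0, 1.0],
            "C2": [10.0, 6.0, 1.0],
            "P1": [15.0, 5.0, 2.0],
            "P2": [10.0, 5.0, 0.5],
            "P3": [5.0, 5.0, 1.0],
        },
        index=["FGF21", "G1", "G2"],
    )
    expr.index.name = "gene_id"
    meta = pd.DataFrame(
        {
            "sample_id": expr.columns,
            "group": ["control", "control", "patient", "patient", "patient"],
            "sex": ["F", "M", "F", "M", "unknown"],
            "steatosis": [np.nan] * 5,
            "lobular_inflammation": [np.nan] * 5,
            "ballooning": [np.nan] * 5,
            "nas": [np.nan] * 5,
            "fibrosis": [np.nan] * 5,
            "study_id": ["S"] * 5,
        }
    ).set_index("sample_id", drop=False)
    return expr, meta
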