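import numpy as np
import pytest

import stiffindex as si
from stiffindex.preprocessing import derive_flags, exclude_asi_outliers, select_cohorts


@pytest.fixture(scope="session")
def small_cohort():
    """Two-arm synthetic cohort at modest size, shared across tests."""
    cfg = si.default_config(n_reference=2000, n_hypertensive=2000, seed=1234)
    return cfg, si.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def processed(small_cohort):
    """Flagged, outlier-filtered and split cohorts with stiffness scores."""
    cfg, cohort = small_cohort
    flagged = derive_flags(cohort)
    filtered, _ = exclude_asi_outliers(flagged)
    reference, analysis, log = select_cohorts(filtered)
    model = si.fit_reference_model(reference)
    scored = analysis.copy()
    result = si.stiffness_index(
        scored["asi_measured"].to_numpy(), model.predict(scored)
    )
    for col in result.columns:
        scored[col] = result[col].to_numpy()
    return {
        "config": cfg,
        "reference": reference,
        "analysis": scored,
        "model": model,
        "log": log,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
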