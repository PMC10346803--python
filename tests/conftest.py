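import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from ehgpreterm import generate_cohort
from ehgpreterm.features import FEATURE_NAMES
from ehgpreterm.io_ehg import META_COLUMNS

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def make_feature_table(n_term: int, n_preterm: int, seed: int = 0,
                       shift: float = 1.0, group: str = "early",
                       n_features: int | None = None) -> pd.DataFrame:
    """Random single-group feature table; preterm rows shifted on half the
    features so screening/classification have signal to find."""
    rng = np.random.default_rng(seed)
    names = list(FEATURE_NAMES[:n_features] if n_features else FEATURE_NAMES)
    rows = []
    for i in range(n_term + n_preterm):
        label = "term" if i < n_term else "preterm"
        values = rng.standard_normal(len(names))
        if label == "preterm":
            values[::2] += shift
        row = {"record_id": f"rec{i:04d}", "label": label, "group": group,
               "provenance": "real"}
        row.update(dict(zip(names, values)))
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + names)


@pytest.fixture(scope="session")
def feature_table_pe_te() -> pd.DataFrame:
    """PE-TE-shaped table: 143 term + 19 preterm real rows."""
    return make_feature_table(143, 19, seed=7)


@pytest.fixture(scope="session")
def cohort_50_50():
    """50 term + 50 preterm full-length synthetic records (defaults)."""
    term = generate_cohort(50, 0, "early", seed=11)
    preterm = generate_cohort(0, 50, "early", seed=12)
    return term, preterm
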