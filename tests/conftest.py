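import numpy as np
import pandas as pd
import pytest

import genecase as gc


@pytest.fixture(scope="session")
def panel():
    return gc.LUNG_PANEL


@pytest.fixture(scope="session")
def expanded_cohort():
    """Individual-level cohort reconstructed from the published per-locus
    genotype counts (819 cases / 803 controls)."""
    return gc.expand_counts_to_cohort(gc.GENOTYPE_COUNTS, seed=1)


@pytest.fixture(scope="session")
def null_cohort():
    """Moderate synthetic cohort with no genetic effects."""
    return gc.simulate_null(gc.SimConfig(n_cases=400, n_controls=400, seed=42))


def make_cohort(doses_by_locus: dict[str, list[int]], status: list[int],
                panel=gc.LUNG_PANEL) -> gc.CohortTable:
    """Hand-built cohort from explicit dose vectors (test helper)."""
    sub_panel = tuple(l for l in panel if l.name in doses_by_locus)
    n = len(status)
    cols = {"id": [f"S{i}" for i in range(n)], "status": status}
    for cov in ("age", "sex", "smoking", "drinking", "copd", "family_history"):
        cols[cov] = np.full(n, np.nan)
    for name, d in doses_by_locus.items():
        cols[name] = d
    return gc.CohortTable(pd.DataFrame(cols), sub_panel)
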