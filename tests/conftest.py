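import numpy as np
import pandas as pd
import pytest

import immunocarto as ic
from immunocarto.discover import ModuleSet
from immunocarto.simulate import DISEASE_ACTIVE_MODULES


@pytest.fixture(scope="session")
def extended_cohort():
    """Default extended-panel cohort (10 diseases incl. healthy), seed 1."""
    cfg = ic.default_config(panel="extended", seed=1)
    raw, truth = ic.generate_cohort(cfg)
    return cfg, raw, truth


@pytest.fixture(scope="session")
def extended_norm(extended_cohort):
    _, raw, _ = extended_cohort
    return ic.normalize_counts(raw)


@pytest.fixture(scope="session")
def true_modules(extended_cohort):
    """ModuleSet built from the planted (truth) gene lists."""
    _, _, truth = extended_cohort
    return ModuleSet({m: list(g) for m, g in truth.module_genes.items()})


@pytest.fixture(scope="session")
def fitted_table(extended_norm, true_modules, extended_cohort):
    _, _, truth = extended_cohort
    return ic.fit_score_table(
        extended_norm.data, true_modules, truth.disease, DISEASE_ACTIVE_MODULES
    )


@pytest.fixture()
def tiny_raw():
    """3-sample, hand-checkable raw counts with depth factors (1, 2, 4)."""
    probes = ["G1", "G2", "HK1", "HK2", "POS1", "POS2", "NEG1"]
    base = np.array([8.0, 32.0, 100.0, 400.0, 50.0, 200.0, 2.0])
    counts = pd.DataFrame(
        [base, 2 * base, 4 * base], index=["s1", "s2", "s3"], columns=probes
    )
    ann = pd.DataFrame(
        {
            "class": [
                "endogenous", "endogenous", "housekeeping", "housekeeping",
                "positive", "positive", "negative",
            ]
        },
        index=pd.Index(probes, name="probe_id"),
    )
    meta = pd.DataFrame(
        {"disease": ["A", "A", "B"]}, index=pd.Index(["s1", "s2", "s3"], name="sample_id")
    )
    return ic.RawCounts(counts=counts, annotation=ann, metadata=meta)
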