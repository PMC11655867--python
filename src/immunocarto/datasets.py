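"""Packaged reference tables."""

from importlib import resources

import pandas as pd


def table2_fixture() -> pd.DataFrame:
    """Published post-treatment module scores of 17 non-responding patients.

    Columns: patient id, age, sex, clinical diagnosis, treatment, Th1 /
    Th2 / Th17 module scores, the printed module-matching status, and the
    re-matched treatment with its response where one was given.
    """
    path = resources.files("immunocarto").joinpath("data/table2_nonresponders.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, dtype={"rematched_treatment_response": "string"})
    return df.set_index("patient_id")
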