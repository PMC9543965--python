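import numpy as np
import pandas as pd
import pytest

from fibropanel import (
    CohortConfig,
    CohortTable,
    VariableSpec,
    default_specs,
    generate_case_control,
)


@pytest.fixture(scope="session")
def specs():
    return default_specs()


@pytest.fixture(scope="session")
def default_cohort(specs):
    return generate_case_control(specs, CohortConfig(seed=7))


@pytest.fixture()
def toy_specs():
    """Two continuous variables and one binary flag over two groups."""
    return [
        VariableSpec("x", "biomarker", "log10normal",
                     {"control": (3.0, 0.2), "t2d": (2.5, 0.3)}, "pg/ml"),
        VariableSpec("y", "mri", "normal",
                     {"control": (60.0, 5.0), "t2d": (70.0, 8.0)}, "mL"),
        VariableSpec("flag", "categorical", "bernoulli",
                     {"control": (0.5,), "t2d": (0.6,)}),
    ]


def make_table(df: pd.DataFrame, schema: dict) -> CohortTable:
    """Assemble a CohortTable from a bare data frame, filling label columns."""
    df = df.copy()
    if "subject_id" not in df:
        df["subject_id"] = [f"S{i}" for i in range(len(df))]
    for col, value in (("group", "t2d"), ("arm", np.nan), ("timepoint", "baseline")):
        if col not in df:
            df[col] = value
    return CohortTable(df, schema)
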