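import pandas as pd
import pytest

from pahrisk import CANONICAL, ConcentrationTable, load_fixture


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_all")


@pytest.fixture(scope="session")
def table2_means(table2):
    return {
        r["analyte"]: r["mean"]
        for _, r in table2.iterrows()
        if r["analyte"] in CANONICAL
    }


@pytest.fixture(scope="session")
def table2_medians(table2):
    return {
        r["analyte"]: r["median"]
        for _, r in table2.iterrows()
        if r["analyte"] in CANONICAL
    }


@pytest.fixture
def tiny_table():
    """Two samples x three analytes, hand-written values."""
    rows = []
    for sid, rep, vals in [
        ("s1", 1, {"Nap": 1.0, "BaP": 0.5, "Py": 2.0}),
        ("s2", 2, {"Nap": 3.0, "BaP": 1.5, "Py": 4.0}),
    ]:
        for analyte, c in vals.items():
            rows.append(
                {
                    "sample_id": sid,
                    "species": "carp",
                    "cooking": "raw",
                    "replicate": rep,
                    "analyte": analyte,
                    "concentration": c,
                }
            )
    return ConcentrationTable(pd.DataFrame(rows))
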