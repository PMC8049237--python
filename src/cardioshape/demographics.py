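"""Demographics of the imaged CT cohort behind the published shape model.

The per-subject table (sex, age in years, weight in kg; two weights
unavailable) ships with the package so cohort-level summary statistics can
be recomputed rather than quoted.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_ct_demographics", "summarize_demographics"]


def load_ct_demographics() -> pd.DataFrame:
    """Per-subject demographics table, indexed by patient identifier."""
    with resources.files("cardioshape.data").joinpath(
        "ct_cohort_demographics.csv"
    ).open() as fh:
        return pd.read_csv(fh, dtype={"patient": str}).set_index("patient")


def summarize_demographics(table: pd.DataFrame = None) -> dict:
    """Mean/SD (sample SD) and range of age and weight, plus sex split."""
    if table is None:
        table = load_ct_demographics()
    out = {}
    for col in ("age", "weight_kg"):
        x = table[col].dropna()
        out[col] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "min": float(x.min()),
            "max": float(x.max()),
            "n": int(x.size),
        }
    out["percent_female"] = 100.0 * float((table["sex"] == "F").mean())
    return out
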