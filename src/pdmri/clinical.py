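"""Reference clinical characteristics of the early-PD patient cohort.

The 19-patient table (gender, age, disease duration in months, UPDRS motor
score, Hoehn & Yahr stage) ships with the package so its descriptive
statistics can be recomputed; all patients are early-stage (H&Y I-II).
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["load_reference_clinical", "descriptive_stats"]

NUMERIC_COLUMNS = ("age_years", "duration_months", "updrs")


def load_reference_clinical() -> pd.DataFrame:
    """The shipped per-patient clinical table (19 rows)."""
    ref = importlib.resources.files("pdmri").joinpath(
        "data/pd_clinical_reference.csv")
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def descriptive_stats(table: pd.DataFrame | None = None) -> dict[str, dict[str, float]]:
    """Mean and sample SD (ddof=1) of age, disease duration and UPDRS."""
    if table is None:
        table = load_reference_clinical()
    out: dict[str, dict[str, float]] = {}
    for col in NUMERIC_COLUMNS:
        values = table[col].astype(float)
        out[col] = {"mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)),
                    "n": int(values.size)}
    return out
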