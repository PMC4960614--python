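"""Collapse a wave-long phenotype table to per-person derived outcomes.

Rules: education is time-invariant and passed through; BMI is the mean over
non-missing waves; height is the max over non-missing waves; heart disease
is 1 if any wave reports it; depressive symptoms are log(mean + 1).
Persons missing a phenotype in every wave keep a missing value for that
phenotype only — they are never dropped globally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["derive_phenotypes", "PERSON_COLUMNS"]

PERSON_COLUMNS = (
    "person_id",
    "household_id",
    "birth_year",
    "educ_years",
    "bmi_mean",
    "height_max",
    "heart_ever",
    "cesd_log",
)

_REQUIRED = (
    "person_id",
    "household_id",
    "birth_year",
    "wave",
    "educ",
    "bmi",
    "height",
    "heart",
    "cesd",
)


def derive_phenotypes(wave_table: pd.DataFrame) -> pd.DataFrame:
    """Per-person phenotype table from a wave-long one.

    Raises on negative BMI/height/CESD values (naming the person) and on
    heart reports outside {0, 1, missing}.
    """
    missing_cols = [c for c in _REQUIRED if c not in wave_table.columns]
    if missing_cols:
        raise ValueError(f"wave table missing columns: {missing_cols}")

    for col in ("bmi", "height", "cesd"):
        bad = wave_table[wave_table[col].notna() & (wave_table[col] < 0)]
        if len(bad):
            pid = bad.iloc[0]["person_id"]
            raise ValueError(f"negative {col} for person {pid}")
    heart = wave_table["heart"]
    if not heart[heart.notna()].isin((0, 1)).all():
        bad = wave_table[heart.notna() & ~heart.isin((0, 1))]
        raise ValueError(
            f"heart report not 0/1 for person {bad.iloc[0]['person_id']}"
        )

    def _heart_ever(values: pd.Series) -> float:
        values = values.dropna()
        if values.empty:
            return np.nan
        return float((values == 1).any())

    grouped = wave_table.groupby("person_id", sort=False)
    out = pd.DataFrame(
        {
            "person_id": grouped["person_id"].first(),
            "household_id": grouped["household_id"].first(),
            "birth_year": grouped["birth_year"].first(),
            "educ_years": grouped["educ"].first(),
            "bmi_mean": grouped["bmi"].mean(),
            "height_max": grouped["height"].max(),
            "heart_ever": grouped["heart"].apply(_heart_ever),
            "cesd_log": np.log1p(grouped["cesd"].mean()),
        }
    )
    return out.reset_index(drop=True)
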