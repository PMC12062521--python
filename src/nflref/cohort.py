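"""Subject-level cohort container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

COLUMNS = ["subject_id", "age_years", "sex", "snfl_pg_ml"]
SEXES = ("M", "F")


@dataclass
class Cohort:
    """An ordered collection of subjects with serum NfL measurements.

    ``data`` is a DataFrame with columns ``subject_id`` (unique strings),
    ``age_years`` (float years), ``sex`` (``"M"``/``"F"``), and
    ``snfl_pg_ml`` (float, strictly positive). ``provenance`` is a free-text
    label (synthetic-config hash or source file path).
    """

    data: pd.DataFrame
    provenance: str = field(default="unspecified")

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort missing columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("cohort must be non-empty")
        if self.data["subject_id"].duplicated().any():
            dupes = self.data.loc[self.data["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject ids: {sorted(set(dupes))[:5]}")
        if (self.data["snfl_pg_ml"] <= 0).any():
            raise ValueError("all sNfL concentrations must be > 0")
        if not self.data["sex"].isin(SEXES).all():
            bad = sorted(set(self.data["sex"]) - set(SEXES))
            raise ValueError(f"sex must be one of {SEXES}, got {bad}")
        self.data = self.data.reset_index(drop=True)[COLUMNS + [c for c in self.data.columns if c not in COLUMNS]]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)
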