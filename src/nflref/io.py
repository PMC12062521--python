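"""Cohort CSV reading/validation and model/table serialization.

Cohort files are plain CSV with header ``subject_id,age_years,sex,snfl_pg_ml``
(sex as M/F, male/female synonyms accepted case-insensitively). Output CSVs
carry ``# key=value`` comment headers recording package version, config hash
and seed so every table is traceable to its run; model JSON stores spline
knots and coefficients at full double precision for bit-stable reload.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .centiles import CentileModel
from .cohort import COLUMNS, Cohort
from .loglinear import LogLinearFit, UpperLimitFormula

__all__ = [
    "ValidationReport",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_table_csv",
    "read_table_csv",
    "save_models",
    "load_models",
]

_SEX_SYNONYMS = {"m": "M", "male": "M", "f": "F", "female": "F"}


@dataclass
class ValidationReport:
    """Row-level outcome of reading a cohort file."""

    n_read: int = 0
    n_accepted: int = 0
    rejections: list[tuple[int, str, str]] = field(default_factory=list)  # (row, field, reason)

    def reject(self, row: int, fld: str, reason: str) -> None:
        self.rejections.append((row, fld, reason))

    @property
    def n_rejected(self) -> int:
        return len({r for r, _, _ in self.rejections})


def read_cohort_csv(
    path: str | Path,
    age_range: tuple[float, float] = (18.0, 70.0),
) -> tuple[Cohort, ValidationReport]:
    """Read and validate a cohort CSV.

    Rows with non-positive concentration, unparsable fields, duplicate
    subject ids, or ages outside ``age_range`` (inclusive; the recruitment
    window) are rejected with per-row reasons. Raises if a required column
    is missing or no row survives validation.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    report = ValidationReport(n_read=len(raw))
    lo, hi = age_range

    keep_rows = []
    seen_ids: set[str] = set()
    for i, row in raw.iterrows():
        rownum = int(i) + 2  # 1-based, counting the header line
        ok = True
        sid = str(row["subject_id"]).strip()
        if not sid or sid.lower() == "nan":
            report.reject(rownum, "subject_id", "missing subject id")
            ok = False
        elif sid in seen_ids:
            report.reject(rownum, "subject_id", f"duplicate subject id {sid!r}")
            ok = False
        try:
            age = float(row["age_years"])
        except (TypeError, ValueError):
            report.reject(rownum, "age_years", f"unparsable age {row['age_years']!r}")
            ok = False
        else:
            if not np.isfinite(age) or not (lo <= age <= hi):
                report.reject(rownum, "age_years", f"age outside {lo:g}-{hi:g}")
                ok = False
        sex = _SEX_SYNONYMS.get(str(row["sex"]).strip().lower())
        if sex is None:
            report.reject(rownum, "sex", f"unrecognized sex {row['sex']!r}")
            ok = False
        try:
            snfl = float(row["snfl_pg_ml"])
        except (TypeError, ValueError):
            report.reject(rownum, "snfl_pg_ml", f"unparsable concentration {row['snfl_pg_ml']!r}")
            ok = False
        else:
            if not np.isfinite(snfl) or snfl <= 0:
                report.reject(rownum, "snfl_pg_ml", "non-positive concentration")
                ok = False
        if ok:
            seen_ids.add(sid)
            keep_rows.append({"subject_id": sid, "age_years": age, "sex": sex, "snfl_pg_ml": snfl})

    report.n_accepted = len(keep_rows)
    if not keep_rows:
        raise ValueError(f"{path}: no rows passed validation ({report.n_read} read)")
    cohort = Cohort(data=pd.DataFrame(keep_rows), provenance=str(path))
    return cohort, report


def _metadata_lines(meta: Optional[dict]) -> str:
    meta = dict(meta or {})
    meta.setdefault("nflref_version", __version__)
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_cohort_csv(cohort: Cohort, path: str | Path, meta: Optional[dict] = None) -> None:
    write_table_csv(cohort.data[COLUMNS], path, meta)


def write_table_csv(df: pd.DataFrame, path: str | Path, meta: Optional[dict] = None) -> None:
    """Write a DataFrame as CSV with a ``# key=value`` metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(meta))
        df.to_csv(fh, index=False)


def read_table_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_models(
    path: str | Path,
    centile_model: Optional[CentileModel] = None,
    loglinear_fit: Optional[LogLinearFit] = None,
    upper_limit: Optional[UpperLimitFormula] = None,
    meta: Optional[dict] = None,
) -> None:
    """Serialize fitted models to one JSON file (lossless roundtrip)."""
    payload: dict = {"meta": dict(meta or {}, nflref_version=__version__)}
    if centile_model is not None:
        payload["centile_model"] = centile_model.to_dict()
    if loglinear_fit is not None:
        payload["loglinear_fit"] = asdict(loglinear_fit)
    if upper_limit is not None:
        payload["upper_limit"] = asdict(upper_limit)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))


def load_models(path: str | Path) -> dict:
    """Inverse of :func:`save_models`; returns a dict with whichever of
    ``centile_model``, ``loglinear_fit``, ``upper_limit`` were stored."""
    payload = json.loads(Path(path).read_text())
    out: dict = {"meta": payload.get("meta", {})}
    if "centile_model" in payload:
        out["centile_model"] = CentileModel.from_dict(payload["centile_model"])
    if "loglinear_fit" in payload:
        out["loglinear_fit"] = LogLinearFit(**payload["loglinear_fit"])
    if "upper_limit" in payload:
        out["upper_limit"] = UpperLimitFormula(**payload["upper_limit"])
    return out
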