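"""Reading and writing subject tables and life tables, and eligibility filters.

Subject tables are delimited text (comma or tab) with one row per study
participant.  Header names are exact; categorical levels are matched
case-insensitively; blank cells map to the covariate's missing/unknown
level.  Life tables are CSV with age-specific disease incidence and
all-cause mortality rates per 100,000 person-years, in 1- or 5-year bands;
loading converts to per-person-year hazards on an annual grid (5-year bands
are expanded under a constant-hazard assumption).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SubjectRecord", "LifeTable", "read_subjects", "write_subjects",
           "read_life_table", "apply_exclusions", "SchemaError"]


class SchemaError(ValueError):
    """A mandatory column is absent or the header does not match the contract."""


# Level vocabularies (canonical spellings; parsing is case-insensitive).
LEVELS = {
    "status": ("case", "control"),
    "design": ("cohort", "case_control"),
    "sex": ("male", "female"),
    "age_cat": ("<50", "51-60", "61-65", "66-70", "71-75", "76-80", "81+"),
    "smoking": ("never", "former", "current", "missing"),
    "diabetes": ("never", "gt3y", "unknown"),
    "family_history": ("no", "yes", "missing"),
    "heavy_alcohol": ("no", "yes", "missing"),
    "bmi_cat": ("under18.5", "18.5-25", "25-30", "over30", "missing"),
    "abo": ("OO", "AO", "AA", "BO", "BB", "AB"),
}

# blank cells in these columns become the covariate's own missing level
_BLANK_LEVEL = {"smoking": "missing", "diabetes": "unknown",
                "family_history": "missing", "heavy_alcohol": "missing",
                "bmi_cat": "missing"}

COLUMNS = ("id", "status", "design", "study", "sex", "age_cat", "smoking",
           "diabetes", "diabetes_lag_years", "family_history", "heavy_alcohol",
           "bmi_cat", "abo", "rs505922_alleles", "rs8176746_alleles",
           "snp_1q32", "snp_5p15", "snp_13q22", "ancestry")

_OPTIONAL_COLUMNS = {"diabetes_lag_years", "abo", "rs505922_alleles",
                     "rs8176746_alleles"}


@dataclass
class SubjectRecord:
    """One case or control with categorical risk factors and genotypes."""

    id: str
    status: str
    design: str
    study: str
    sex: str
    age_cat: str
    smoking: str = "missing"
    diabetes: str = "unknown"
    diabetes_lag_years: float | None = None
    family_history: str = "missing"
    heavy_alcohol: str = "missing"
    bmi_cat: str = "missing"
    abo: str | None = None
    rs505922_alleles: int | None = None
    rs8176746_alleles: int | None = None
    snp_1q32: int | None = None
    snp_5p15: int | None = None
    snp_13q22: int | None = None
    ancestry: str = "european"

    def __post_init__(self) -> None:
        for name, levels in LEVELS.items():
            value = getattr(self, name)
            if value is None and name in ("abo",):
                continue
            if value not in levels:
                raise ValueError(f"record {self.id}: invalid {name} level {value!r}")
        for name in ("rs505922_alleles", "rs8176746_alleles",
                     "snp_1q32", "snp_5p15", "snp_13q22"):
            value = getattr(self, name)
            if value is not None and int(value) not in (0, 1, 2):
                raise ValueError(f"record {self.id}: {name}={value!r} not in 0..2")
        if self.diabetes_lag_years is not None:
            if self.status != "case" or self.diabetes == "never":
                raise ValueError(
                    f"record {self.id}: diabetes lag only applies to diabetic cases")
            if self.diabetes_lag_years < 0:
                raise ValueError(f"record {self.id}: negative diabetes lag")


def _parse_level(column: str, raw: str, row_no: int) -> str:
    raw = raw.strip()
    if raw == "" and column in _BLANK_LEVEL:
        return _BLANK_LEVEL[column]
    for level in LEVELS[column]:
        if raw.lower() == level.lower():
            return level
    raise ValueError(f"row {row_no}, column {column!r}: invalid level {raw!r}")


def _parse_opt_int(column: str, raw: str, row_no: int) -> int | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return int(raw)
    except ValueError as exc:
        raise ValueError(f"row {row_no}, column {column!r}: {raw!r} "
                         f"is not an integer") from exc


def read_subjects(path, dialect: str | None = None) -> list[SubjectRecord]:
    """Read a delimited subject table into records.

    ``dialect`` is a delimiter (',' or '\\t'); by default it is sniffed from
    the header line.  Blank cells map to the covariate's missing/unknown
    level; unparseable levels raise with the offending row and column.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        head = fh.readline()
        delim = dialect or ("\t" if "\t" in head else ",")
        header = [h.strip() for h in head.rstrip("\n").split(delim)]
        missing = [c for c in COLUMNS if c not in header and c not in _OPTIONAL_COLUMNS]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        reader = csv.DictReader(fh, fieldnames=header, delimiter=delim)
        records = []
        for row_no, row in enumerate(reader, start=2):
            kw: dict = {"id": row["id"].strip(), "study": row["study"].strip(),
                        "ancestry": row.get("ancestry", "european").strip()
                        or "european"}
            for col in LEVELS:
                if col == "abo":
                    raw = row.get("abo", "").strip()
                    kw["abo"] = _parse_level("abo", raw, row_no) if raw else None
                else:
                    kw[col] = _parse_level(col, row[col], row_no)
            for col in ("rs505922_alleles", "rs8176746_alleles",
                        "snp_1q32", "snp_5p15", "snp_13q22"):
                kw[col] = _parse_opt_int(col, row.get(col, ""), row_no)
            lag = row.get("diabetes_lag_years", "").strip()
            kw["diabetes_lag_years"] = float(lag) if lag else None
            records.append(SubjectRecord(**kw))
    return records


def write_subjects(records: Iterable[SubjectRecord], path,
                   dialect: str = "\t") -> None:
    """Write records as a delimited table using the documented header."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect)
        writer.writerow(COLUMNS)
        for r in records:
            row = []
            for col in COLUMNS:
                value = getattr(r, col)
                row.append("" if value is None else value)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Eligibility filters

def apply_exclusions(records: Sequence[SubjectRecord]
                     ) -> tuple[list[SubjectRecord], list[tuple[SubjectRecord, str]]]:
    """Apply the analysis eligibility filters.

    Excludes (a) participants of non-European ancestry and (b) cases whose
    diabetes was diagnosed within 3 years of the cancer diagnosis (possible
    reverse causation).  Returns (kept, excluded-with-reason); order of
    kept records is preserved and the filter is idempotent.
    """
    kept: list[SubjectRecord] = []
    excluded: list[tuple[SubjectRecord, str]] = []
    for r in records:
        if r.ancestry.lower() not in ("european", "non-hispanic white"):
            excluded.append((r, "ancestry"))
        elif (r.status == "case" and r.diabetes_lag_years is not None
              and r.diabetes_lag_years < 3):
            excluded.append((r, "recent-onset diabetes"))
        else:
            kept.append(r)
    return kept, excluded


# ---------------------------------------------------------------------------
# Life tables

@dataclass
class LifeTable:
    """Per-sex, per-year disease incidence and all-cause mortality hazards.

    ``ages`` are contiguous integer attained ages; ``incidence`` and
    ``mortality`` are per-person-year hazards (events per person-year),
    each in [0, 1).  Intervals downstream are half-open [a1, a2).
    """

    sex: str
    ages: np.ndarray
    incidence: np.ndarray
    mortality: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.mortality = np.asarray(self.mortality, dtype=float)
        if not (len(self.ages) == len(self.incidence) == len(self.mortality)):
            raise ValueError("age/incidence/mortality lengths differ")
        if len(self.ages) and np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be contiguous at one-year resolution")
        for name, arr in (("incidence", self.incidence),
                          ("mortality", self.mortality)):
            if np.any(arr < 0) or np.any(arr >= 1):
                raise ValueError(f"{name} hazards must lie in [0, 1)")

    def slice(self, start_age: int, end_age: int) -> tuple[np.ndarray, np.ndarray]:
        """(incidence, mortality) hazard arrays over [start_age, end_age)."""
        if start_age < self.ages[0] or end_age > self.ages[-1] + 1:
            raise ValueError(f"ages [{start_age}, {end_age}) outside the "
                             f"table support [{self.ages[0]}, {self.ages[-1]}]")
        i0 = start_age - self.ages[0]
        i1 = end_age - self.ages[0]
        return self.incidence[i0:i1], self.mortality[i0:i1]


def read_life_table(path, sex: str | None = None) -> LifeTable:
    """Load a life-table CSV into per-person-year hazards on an annual grid.

    Expected columns: ``age`` (or ``age_start``/``age_end``), ``sex``,
    ``incidence_per_100k``, ``mortality_per_100k``.  Rates are divided by
    1e5; 5-year (or any multi-year) bands are expanded to constant per-year
    hazards.  Overlapping or gapped bands raise a validation error.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"sex", "incidence_per_100k", "mortality_per_100k"}
    if not required <= set(df.columns):
        raise SchemaError(f"life table needs columns {sorted(required)} "
                          f"plus age or age_start/age_end")
    if sex is not None:
        df = df[df["sex"].str.lower() == sex.lower()]
        if df.empty:
            raise ValueError(f"no rows for sex {sex!r}")
    sexes = df["sex"].str.lower().unique()
    if len(sexes) != 1:
        raise ValueError(f"life table mixes sexes {list(sexes)}; pass sex=")
    if (df["incidence_per_100k"] < 0).any() or (df["mortality_per_100k"] < 0).any():
        raise ValueError("negative rate in life table")

    if "age" in df.columns:
        starts = df["age"].astype(int).to_numpy()
        ends = starts + 1
    elif {"age_start", "age_end"} <= set(df.columns):
        starts = df["age_start"].astype(int).to_numpy()
        ends = df["age_end"].astype(int).to_numpy() + 1  # inclusive band end
    else:
        raise SchemaError("life table needs an age or age_start/age_end column")

    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    inc = df["incidence_per_100k"].to_numpy()[order] / 1e5
    mort = df["mortality_per_100k"].to_numpy()[order] / 1e5
    if np.any(ends[:-1] != starts[1:]):
        raise ValueError("life-table age bands overlap or leave gaps")

    ages, inc_y, mort_y = [], [], []
    for a0, a1, hi, hm in zip(starts, ends, inc, mort):
        for a in range(a0, a1):
            ages.append(a)
            inc_y.append(hi)   # constant hazard across the band
            mort_y.append(hm)
    return LifeTable(sex=str(df["sex"].iloc[0]).lower(), ages=np.array(ages),
                     incidence=np.array(inc_y), mortality=np.array(mort_y))
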