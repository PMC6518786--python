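"""Reading, validating and aggregating death-record tables.

The canonical in-memory representation of a set of death records is a
:class:`pandas.DataFrame` with columns

* ``time_of_day`` — integer minutes since midnight, in ``[0, 1440)``
* ``cause`` — one of :data:`CAUSES`
* ``age`` — integer years
* ``sex`` — ``male`` or ``female``
* ``race`` — optional free categorical

Input files are delimited text with a header; a plain-text (YAML) schema
config maps arbitrary column names and category labels onto the canonical
ones, since registry extracts differ in layout.  Rows that cannot be
validated are rejected and counted, never imputed or silently zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("circmort")

CAUSES = ("cancer", "ischemic_heart_disease", "pneumonia", "other")
SEXES = ("male", "female")

MINUTES_PER_DAY = 1440
HOURS_PER_DAY = 24

_CANONICAL_COLUMNS = ["time_of_day", "cause", "age", "sex"]


@dataclass
class Schema:
    """Column and label mapping for a record file.

    ``cause_map`` / ``sex_map`` translate raw labels (lower-cased, stripped)
    to canonical categories; unmapped labels reject the row.  Canonical
    labels always map to themselves.
    """

    time: str = "time"
    cause: str = "cause"
    age: str = "age"
    sex: str = "sex"
    race: str | None = None
    cause_map: dict[str, str] = field(default_factory=dict)
    sex_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Schema":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cols = raw.get("columns", {})
        return cls(
            time=cols.get("time", "time"),
            cause=cols.get("cause", "cause"),
            age=cols.get("age", "age"),
            sex=cols.get("sex", "sex"),
            race=cols.get("race"),
            cause_map={str(k).lower(): v for k, v in (raw.get("cause_map") or {}).items()},
            sex_map={str(k).lower(): v for k, v in (raw.get("sex_map") or {}).items()},
        )


@dataclass
class HourlyCounts:
    """Deaths per clock hour; bin ``h`` covers the half-open ``[h:00, h+1:00)``."""

    counts: np.ndarray
    cause: str | None = None
    n: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (HOURS_PER_DAY,):
            raise ValueError("hourly counts must have exactly 24 bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            self.n = int(self.counts.sum())
        elif self.n != int(self.counts.sum()):
            raise ValueError("n does not match sum of counts")


def _parse_times(raw: pd.Series) -> pd.Series:
    """Minutes since midnight from HH:MM, HH:MM:SS or ISO date-times (NaN if unparseable)."""
    s = raw.astype("string").str.strip()
    # bare clock times: prepend a dummy date so a single vectorised parse suffices
    bare = s.str.match(r"^\d{1,2}:\d{2}(:\d{2})?$", na=False)
    s = s.where(~bare, "1970-01-01 " + s)
    dt = pd.to_datetime(s, errors="coerce", format="mixed")
    return dt.dt.hour * 60 + dt.dt.minute


def read_records(
    path: str | Path,
    schema: Schema | None = None,
    sep: str = ",",
    age_range: tuple[int, int] = (0, 120),
) -> tuple[pd.DataFrame, int]:
    """Read a delimited record file into the canonical frame.

    Returns ``(records, n_rejected)``.  A missing mandatory column is a hard
    error naming the column; individually invalid rows (unparseable or
    out-of-range time, unmapped cause or sex, missing or negative age) are
    rejected with a logged reason.  Ages outside ``age_range`` are kept but
    warned about.
    """
    schema = schema or Schema()
    raw = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    for attr in ("time", "cause", "age", "sex"):
        col = getattr(schema, attr)
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column {col!r} (maps to {attr})")

    n_in = len(raw)
    time_of_day = _parse_times(raw[schema.time])
    ok_time = time_of_day.notna() & (time_of_day >= 0) & (time_of_day < MINUTES_PER_DAY)

    cause_raw = raw[schema.cause].astype("string").str.strip().str.lower()
    cause = cause_raw.map(lambda c: schema.cause_map.get(c, c) if pd.notna(c) else c)
    ok_cause = cause.isin(CAUSES)

    sex_raw = raw[schema.sex].astype("string").str.strip().str.lower()
    sex = sex_raw.map(lambda c: schema.sex_map.get(c, c) if pd.notna(c) else c)
    ok_sex = sex.isin(SEXES)

    age = pd.to_numeric(raw[schema.age], errors="coerce")
    ok_age = age.notna() & (age >= 0)

    keep = ok_time & ok_cause & ok_sex & ok_age
    for mask, reason in [
        (~ok_time, "unparseable or out-of-range time"),
        (~ok_cause, "unmapped cause label"),
        (~ok_sex, "unmapped sex label"),
        (~ok_age, "missing or negative age"),
    ]:
        n_bad = int(mask.sum())
        if n_bad:
            logger.warning("rejected %d row(s): %s", n_bad, reason)

    records = pd.DataFrame(
        {
            "time_of_day": time_of_day[keep].astype(np.int64),
            "cause": pd.Categorical(cause[keep], categories=CAUSES),
            "age": age[keep].round().astype(np.int64),
            "sex": pd.Categorical(sex[keep], categories=SEXES),
        }
    ).reset_index(drop=True)
    if schema.race is not None and schema.race in raw.columns:
        records["race"] = raw.loc[keep, schema.race].reset_index(drop=True)

    n_implausible = int(((records["age"] < age_range[0]) | (records["age"] > age_range[1])).sum())
    if n_implausible:
        logger.warning("%d record(s) with age outside plausible range %s", n_implausible, age_range)

    n_rejected = n_in - len(records)
    logger.info("read %d rows, kept %d records, rejected %d", n_in, len(records), n_rejected)
    return records, n_rejected


def write_records(records: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write the canonical frame as delimited text with HH:MM times."""
    out = records.copy()
    t = out["time_of_day"].to_numpy()
    out["time"] = [f"{m // 60:02d}:{m % 60:02d}" for m in t]
    cols = ["time", "cause", "age", "sex"] + (["race"] if "race" in out.columns else [])
    out[cols].to_csv(path, sep=sep, index=False)


def validate_records(records: pd.DataFrame) -> None:
    """Raise if the frame violates the canonical-record invariants."""
    missing = [c for c in _CANONICAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing canonical column(s): {missing}")
    t = records["time_of_day"]
    if len(t) and (t.min() < 0 or t.max() >= MINUTES_PER_DAY):
        raise ValueError("time_of_day out of [0, 1440)")
    if len(records) and (records["age"] < 0).any():
        raise ValueError("negative age")


def aggregate_counts(
    records: pd.DataFrame,
    resolution: str = "hour",
    cause: str | None = None,
):
    """Bin records into hourly (:class:`HourlyCounts`) or minute (1440-vector) counts.

    An empty selection yields all-zero counts, not an error.
    """
    validate_records(records)
    sel = records if cause is None else records[records["cause"] == cause]
    t = sel["time_of_day"].to_numpy()
    if resolution == "hour":
        counts = np.bincount(t // 60, minlength=HOURS_PER_DAY)
        return HourlyCounts(counts=counts, cause=cause)
    if resolution == "minute":
        return np.bincount(t, minlength=MINUTES_PER_DAY)
    raise ValueError(f"unknown resolution {resolution!r}")


def minutes_to_hours(minute_counts: np.ndarray, cause: str | None = None) -> HourlyCounts:
    """Re-bin a 1440-vector of minute counts into hourly counts."""
    minute_counts = np.asarray(minute_counts)
    if minute_counts.shape != (MINUTES_PER_DAY,):
        raise ValueError("expected a 1440-vector of minute counts")
    return HourlyCounts(counts=minute_counts.reshape(HOURS_PER_DAY, 60).sum(axis=1), cause=cause)
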