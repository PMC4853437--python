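"""Reading, validation and writing of the three tabular inputs.

The pipeline consumes three plain CSV files:

``scans.csv``
    One row per (scan, individual): ``scan_id,date,time,individual,x,y,visible``.
    Coordinates are metres on the 30 x 30 m observation grid, stored as
    1-m cell centres (cell (5, 3) -> (5.5, 3.5)).  Out-of-sight individuals
    appear as rows with ``visible = False`` and empty coordinates, never by
    absence, so "not scanned" and "in the forest" stay distinguishable.

``agonistic.csv``
    ``timestamp,actor,receiver,behavior,n_participants,clear_outcome``.
    Behavior codes are opaque labels.

``individuals.csv``
    ``id,sex,birth_date,age,matriline``.  Ages in years; matriline may be
    missing.

Validation is strict: rows off the grid, duplicate (scan, individual) pairs
and unknown individual ids raise :class:`ValidationError` with row-level
diagnostics rather than being silently dropped.
"""

from __future__ import annotations

import dataclasses
from datetime import time as dtime

import numpy as np
import pandas as pd

GRID_SIZE = 30.0  # metres; observation area is [0, 30] x [0, 30]

#: Observation windows; 12:00 belongs to the morning block.
AM_WINDOW = (dtime(9, 0), dtime(12, 0))
PM_WINDOW = (dtime(15, 0), dtime(18, 0))

#: Age-class boundary used for mean-imputation of missing ages.  Individuals
#: aged within [5, SUBADULT_MAX_AGE] are subadults, older ones adults.  The
#: boundary is a convention (see docs/methods.md) and is overridable wherever
#: age classes are derived.
SUBADULT_MAX_AGE = 7.0
MIN_STUDY_AGE = 5.0


class ValidationError(ValueError):
    """Input data violates a schema or study-design invariant."""


@dataclasses.dataclass
class ScanTable:
    """Validated per-scan positions; the single source of spatial metrics
    and associations.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns ``scan_id, date, time, period, individual, x, y, visible``.
        ``period`` is "am" or "pm", derived from ``time``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _validate_scan_frame(self.df)

    @property
    def n_scans(self) -> int:
        return self.df["scan_id"].nunique()

    def individuals(self) -> list[str]:
        return sorted(self.df["individual"].unique())

    def visible(self) -> pd.DataFrame:
        """Rows where the individual was seen inside the area."""
        return self.df[self.df["visible"]]

    def period(self, which: str) -> "ScanTable":
        """Restrict to the am or pm observation block."""
        if which not in ("am", "pm"):
            raise ValueError(f"period must be 'am' or 'pm', got {which!r}")
        out = object.__new__(ScanTable)
        out.df = self.df[self.df["period"] == which].reset_index(drop=True)
        return out


def derive_period(t: dtime) -> str:
    """Classify a time of day into the am (09:00-12:00, 12:00 inclusive)
    or pm (15:00-18:00) observation block."""
    if AM_WINDOW[0] <= t <= AM_WINDOW[1]:
        return "am"
    if PM_WINDOW[0] <= t <= PM_WINDOW[1]:
        return "pm"
    raise ValidationError(f"time {t} outside observation windows 09:00-12:00 / 15:00-18:00")


def _validate_scan_frame(df: pd.DataFrame) -> pd.DataFrame:
    required = {"scan_id", "date", "time", "individual", "x", "y", "visible"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"scan table missing columns: {sorted(missing)}")
    df = df.copy()
    df["scan_id"] = df["scan_id"].astype(int)
    df["individual"] = df["individual"].astype(str)
    df["visible"] = df["visible"].astype(bool)
    df["x"] = pd.to_numeric(df["x"])
    df["y"] = pd.to_numeric(df["y"])

    df["date"] = df["date"].astype(str)
    times = df["time"].apply(_coerce_time)
    df["time"] = times
    if "period" not in df.columns:
        df["period"] = times.apply(derive_period)

    dup = df.duplicated(subset=["scan_id", "individual"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["scan_id", "individual"]].drop_duplicates()
        detail = "; ".join(f"scan {s} individual {i}" for s, i in pairs.itertuples(index=False))
        raise ValidationError(f"duplicate (scan_id, individual) records: {detail}")

    vis = df["visible"]
    bad_missing = vis & (df["x"].isna() | df["y"].isna())
    if bad_missing.any():
        raise ValidationError(
            f"{int(bad_missing.sum())} visible rows lack coordinates "
            f"(rows {df.index[bad_missing].tolist()[:10]})"
        )
    oob = vis & ~(
        (df["x"] >= 0) & (df["x"] <= GRID_SIZE) & (df["y"] >= 0) & (df["y"] <= GRID_SIZE)
    )
    if oob.any():
        rows = df.loc[oob, ["scan_id", "individual", "x", "y"]]
        detail = "; ".join(
            f"scan {r.scan_id} {r.individual} at ({r.x}, {r.y})" for r in rows.itertuples()
        )
        raise ValidationError(f"coordinates outside the {GRID_SIZE:g} m grid: {detail}")
    invis = ~vis
    df.loc[invis, ["x", "y"]] = np.nan
    return df.reset_index(drop=True)


def _coerce_time(value) -> dtime:
    if isinstance(value, dtime):
        return value
    return pd.Timestamp(f"2000-01-01 {value}").time()


def read_scan_table(path, known_ids=None) -> ScanTable:
    """Read and validate ``scans.csv``.

    Parameters
    ----------
    path : str or Path
    known_ids : iterable of str, optional
        Roster of valid individual ids; any scan row naming an id outside
        the roster raises :class:`ValidationError`.
    """
    df = pd.read_csv(path, dtype={"individual": str})
    table = ScanTable(df)
    if known_ids is not None:
        known = set(map(str, known_ids))
        unknown = sorted(set(table.df["individual"]) - known)
        if unknown:
            raise ValidationError(f"scan table references unknown individual ids: {unknown}")
    return table


def write_scan_table(table: ScanTable, path) -> None:
    df = table.df.copy()
    df["time"] = df["time"].apply(lambda t: t.strftime("%H:%M"))
    df.drop(columns=["period"]).to_csv(path, index=False)


def read_individuals(path) -> pd.DataFrame:
    """Read ``individuals.csv`` into a metadata frame indexed by row.

    Returns a frame with columns ``id, sex, birth_date, age, matriline`` and
    a derived ``age_class`` ("subadult" / "adult", NaN while age missing).
    """
    df = pd.read_csv(path, dtype={"id": str, "matriline": str})
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"])
        raise ValidationError(f"duplicate individual ids: {dupes}")
    bad_sex = ~df["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise ValidationError(f"sex must be F or M; offending ids: {df.loc[bad_sex, 'id'].tolist()}")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if (df["age"].dropna() < 0).any():
        raise ValidationError("negative ages present")
    df["age_class"] = assign_age_classes(df["age"])
    return df


def write_individuals(df: pd.DataFrame, path) -> None:
    cols = ["id", "sex", "birth_date", "age", "matriline"]
    df[[c for c in cols if c in df.columns]].to_csv(path, index=False)


def assign_age_classes(ages: pd.Series, subadult_max_age: float = SUBADULT_MAX_AGE) -> pd.Series:
    """Map ages to {"subadult", "adult"}; NaN ages stay NaN."""
    cls = pd.Series(pd.NA, index=ages.index, dtype="object")
    cls[ages.notna() & (ages <= subadult_max_age)] = "subadult"
    cls[ages.notna() & (ages > subadult_max_age)] = "adult"
    return cls


def read_agonistic(path, known_ids=None) -> pd.DataFrame:
    """Read and validate ``agonistic.csv``."""
    df = pd.read_csv(path, dtype={"actor": str, "receiver": str, "behavior": str})
    required = {"timestamp", "actor", "receiver", "behavior", "n_participants", "clear_outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"agonistic table missing columns: {sorted(missing)}")
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["n_participants"] = df["n_participants"].astype(int)
    df["clear_outcome"] = df["clear_outcome"].astype(bool)
    self_agg = df["actor"] == df["receiver"]
    if self_agg.any():
        raise ValidationError(f"actor == receiver in rows {df.index[self_agg].tolist()}")
    if (df["n_participants"] < 2).any():
        raise ValidationError("n_participants must be >= 2")
    if known_ids is not None:
        known = set(map(str, known_ids))
        unknown = sorted((set(df["actor"]) | set(df["receiver"])) - known)
        if unknown:
            raise ValidationError(f"agonistic table references unknown ids: {unknown}")
    return df


def write_agonistic(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def apply_study_filters(individuals: pd.DataFrame, min_age: float = MIN_STUDY_AGE):
    """Apply the juvenile-exclusion rule: keep individuals aged >= ``min_age``.

    Juveniles spend their time with their mothers and have unstable
    relationships, so they are excluded from all analyses.

    Returns
    -------
    included : list of str
        Sorted ids of retained individuals.
    report : dict
        ``{"n_input", "n_included", "n_excluded", "excluded_ids"}``.
    """
    ages = individuals["age"]
    if ages.isna().any():
        missing = individuals.loc[ages.isna(), "id"].tolist()
        raise ValidationError(
            f"ages missing for {missing}; run impute_missing_ages first"
        )
    keep = ages >= min_age
    included = sorted(individuals.loc[keep, "id"])
    if not included:
        raise ValidationError("age filter removed every individual")
    report = {
        "n_input": int(len(individuals)),
        "n_included": int(keep.sum()),
        "n_excluded": int((~keep).sum()),
        "excluded_ids": sorted(individuals.loc[~keep, "id"]),
    }
    return included, report


def impute_missing_ages(
    individuals: pd.DataFrame, subadult_max_age: float = SUBADULT_MAX_AGE
) -> pd.DataFrame:
    """Replace missing ages with the mean age of the individual's age class.

    Each missing-age individual must carry an ``age_class`` with at least one
    observed age; the returned frame flags imputed rows in ``age_imputed``.
    """
    df = individuals.copy()
    if "age_class" not in df.columns:
        df["age_class"] = assign_age_classes(df["age"], subadult_max_age)
    df["age_imputed"] = False
    missing = df["age"].isna()
    if not missing.any():
        return df
    if df.loc[missing, "age_class"].isna().any():
        bad = df.loc[missing & df["age_class"].isna(), "id"].tolist()
        raise ValidationError(f"missing age and no age class for: {bad}")
    class_means = df.loc[~missing].groupby("age_class")["age"].mean()
    for cls in df.loc[missing, "age_class"].unique():
        if cls not in class_means.index:
            raise ValidationError(f"no observed ages in class {cls!r} to impute from")
    df.loc[missing, "age"] = df.loc[missing, "age_class"].map(class_means)
    df.loc[missing, "age_imputed"] = True
    return df


def write_matrix_csv(matrix: np.ndarray, ids, path) -> None:
    """Write a labelled square matrix as CSV (ids as header and index)."""
    pd.DataFrame(np.asarray(matrix), index=list(ids), columns=list(ids)).to_csv(path)


def read_matrix_csv(path):
    """Read a labelled square matrix; returns (matrix, ids)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValidationError("matrix CSV row and column labels differ")
    return df.to_numpy(dtype=float), [str(i) for i in df.columns]
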