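"""Event-record data model: reading, validation, exclusion audit and
descriptive summaries of agricultural extension training events.

One record is one village-level training session with aggregated male and
female attendee counts plus six categorical descriptors of when, where and
by whom the training was delivered.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

#: Categorical fields, in canonical order, with their closed level sets.
#: The first level of each factor is the default reference level for
#: dummy coding downstream.
DEFAULT_SCHEMA: dict[str, tuple[str, ...]] = {
    "trainer_gender": ("female", "male"),
    "time_bin": ("before_11", "11_to_1530", "after_1530"),
    "day_of_week": (
        "sunday", "monday", "tuesday", "wednesday",
        "thursday", "friday", "saturday",
    ),
    "month": ("oct2018", "nov2018", "dec2018", "jan2019"),
    "venue": (
        "educational_institution", "farmers_house", "marketplace",
        "religious_institution", "shop", "tea_stall", "union_parishad",
        "other",
    ),
    "division": ("rangpur", "khulna", "dhaka", "rajshahi"),
}

FACTORS: tuple[str, ...] = tuple(DEFAULT_SCHEMA)
COUNT_COLUMNS: tuple[str, ...] = ("males", "females")
COLUMNS: tuple[str, ...] = FACTORS + COUNT_COLUMNS

_norm_re = re.compile(r"[^a-z0-9]+")


def normalize_label(label: str) -> str:
    """Normalize a category label to lower_snake_case."""
    return _norm_re.sub("_", str(label).strip().lower()).strip("_")


@dataclass
class EventTable:
    """Validated event records plus the raw rows that failed validation.

    ``df`` holds one row per valid event with columns :data:`COLUMNS`;
    ``excluded`` holds the raw offending rows with a ``reason`` column.
    Source-file row order is preserved in both.
    """

    df: pd.DataFrame
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(COLUMNS) + ["reason"])
    )

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")

    @property
    def n_events(self) -> int:
        return len(self.df)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def total_attendance(self) -> int:
        return int(self.df["males"].sum() + self.df["females"].sum())


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _validate_rows(raw: pd.DataFrame, schema: dict[str, tuple[str, ...]]):
    """Split raw string-typed rows into valid records and reasons.

    Validation order per row: any missing/unparseable field excludes the
    whole row (``missing_information``), then negative counts
    (``negative_count``), then categorical values outside the schema
    (``unknown_level``).
    """
    level_sets = {f: set(levels) for f, levels in schema.items()}
    records, reasons = [], []
    for _, row in raw.iterrows():
        reason = None
        rec: dict[str, object] = {}
        for col in COLUMNS:
            val = row[col]
            if pd.isna(val) or str(val).strip() == "":
                reason = "missing_information"
                break
            rec[col] = str(val).strip()
        if reason is None:
            for col in COUNT_COLUMNS:
                try:
                    x = float(rec[col])
                except ValueError:
                    reason = "missing_information"
                    break
                if not np.isfinite(x) or x != int(x):
                    reason = "missing_information"
                    break
                if x < 0:
                    reason = "negative_count"
                    break
                rec[col] = int(x)
        if reason is None:
            for f in FACTORS:
                lvl = normalize_label(rec[f])
                if lvl not in level_sets[f]:
                    reason = "unknown_level"
                    break
                rec[f] = lvl
        records.append(rec if reason is None else None)
        reasons.append(reason)
    return records, reasons


def events_from_frame(raw: pd.DataFrame,
                      schema: dict[str, tuple[str, ...]] | None = None) -> EventTable:
    """Validate an in-memory raw frame into an :class:`EventTable`."""
    schema = schema or DEFAULT_SCHEMA
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"input is missing required columns: {missing}")
    records, reasons = _validate_rows(raw[list(COLUMNS)], schema)
    good = [r for r in records if r is not None]
    bad_mask = [r is None for r in records]
    df = pd.DataFrame(good, columns=list(COLUMNS))
    if len(df):
        for f in FACTORS:
            df[f] = pd.Categorical(df[f], categories=schema[f])
        df[["males", "females"]] = df[["males", "females"]].astype(np.int64)
    excluded = raw.loc[bad_mask, list(COLUMNS)].copy()
    excluded["reason"] = [r for r in reasons if r is not None]
    return EventTable(df=df.reset_index(drop=True),
                      excluded=excluded.reset_index(drop=True))


def read_events(path, schema: dict[str, tuple[str, ...]] | None = None) -> EventTable:
    """Read an events CSV, validating every row against the schema.

    Well-formed rows become events; rows with any missing or unparseable
    field, negative counts or unknown categorical levels are routed to
    ``excluded`` with a reason code. Source row order is preserved.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    return events_from_frame(raw, schema)


def write_events(table: EventTable, path) -> None:
    """Write included rows as CSV in schema column order (round-trips)."""
    table.df.to_csv(path, index=False, columns=list(COLUMNS))


# ---------------------------------------------------------------------------
# Exclusion audit
# ---------------------------------------------------------------------------

def audit_exclusions(table: EventTable) -> dict:
    """Audit excluded rows: exclusion rate and Welch two-sample t-tests.

    Compares mean male and mean female attendance between included and
    excluded rows (unequal-variance t-test), wherever the excluded raw
    rows carry parseable counts. Degenerate cases are reported as
    ``not computable`` rather than raised.

    Both the included-attendance total and the grand total including
    parseable excluded rows are exposed without reconciliation.
    """
    n_inc, n_exc = table.n_events, table.n_excluded
    n_all = n_inc + n_exc
    report: dict = {
        "n_included": n_inc,
        "n_excluded": n_exc,
        "exclusion_percent": 100.0 * n_exc / n_all if n_all else float("nan"),
        "included_attendance_total": table.total_attendance() if n_inc else 0,
    }
    grand = report["included_attendance_total"]
    for col in COUNT_COLUMNS:
        exc_vals = pd.to_numeric(table.excluded.get(col, pd.Series(dtype=float)),
                                 errors="coerce").dropna().to_numpy(dtype=float)
        grand += exc_vals.sum()
        inc_vals = table.df[col].to_numpy(dtype=float)
        key = f"{col}_test"
        if len(inc_vals) < 2 or len(exc_vals) < 2:
            report[key] = {"status": "not computable"}
            continue
        if np.ptp(inc_vals) == 0 and np.ptp(exc_vals) == 0 and inc_vals[0] == exc_vals[0]:
            # identical constant groups: zero difference by convention
            report[key] = {"status": "ok", "statistic": 0.0, "p_value": 1.0}
            continue
        t, p = stats.ttest_ind(inc_vals, exc_vals, equal_var=False)
        report[key] = {"status": "ok", "statistic": float(t), "p_value": float(p)}
    report["grand_attendance_total"] = float(grand)
    return report


def write_audit(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

def _sd(x: np.ndarray) -> float:
    # sample SD (n-1); a single observation reports 0 by convention
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def summarize_events(table: EventTable, factor: str) -> pd.DataFrame:
    """Per-level descriptive statistics for one categorical factor.

    Returns one row per level: event count, percent of events, and
    mean/SD/min/max of male and of female attendance. ``single_obs``
    flags levels where the SD of one observation was reported as 0.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    if table.n_events == 0:
        raise ValueError("no data")
    rows = []
    n_total = table.n_events
    for level in table.df[factor].cat.categories:
        sub = table.df[table.df[factor] == level]
        m = sub["males"].to_numpy(dtype=float)
        f = sub["females"].to_numpy(dtype=float)
        rows.append({
            "level": level,
            "n_events": len(sub),
            "percent": 100.0 * len(sub) / n_total,
            "males_mean": float(m.mean()) if len(m) else np.nan,
            "males_sd": _sd(m) if len(m) else np.nan,
            "males_min": float(m.min()) if len(m) else np.nan,
            "males_max": float(m.max()) if len(m) else np.nan,
            "females_mean": float(f.mean()) if len(f) else np.nan,
            "females_sd": _sd(f) if len(f) else np.nan,
            "females_min": float(f.min()) if len(f) else np.nan,
            "females_max": float(f.max()) if len(f) else np.nan,
            "single_obs": len(sub) == 1,
        })
    out = pd.DataFrame(rows)
    out.attrs["factor"] = factor
    out.attrs["mean_total_attendance"] = float(
        (table.df["males"] + table.df["females"]).mean())
    out.attrs["mean_female_attendance"] = float(table.df["females"].mean())
    return out
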