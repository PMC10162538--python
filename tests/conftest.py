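"""Shared fixtures: programmatically built event tables mirroring the
study's published descriptive counts, plus small synthetic tables."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from agritrain.events import COLUMNS, DEFAULT_SCHEMA, events_from_frame

DIVISION_COUNTS = {"rangpur": 527, "khulna": 295, "dhaka": 202, "rajshahi": 43}
N_RAW = 1080
N_EXCLUDED = 13


def _study_raw_frame() -> pd.DataFrame:
    """1,080 raw rows: 1,067 valid events with the published division
    breakdown plus 13 rows with a blank count field."""
    rows = []
    cyc = {f: itertools.cycle(DEFAULT_SCHEMA[f])
           for f in ("trainer_gender", "time_bin", "day_of_week", "month",
                     "venue")}
    rng = np.random.default_rng(20181001)
    for division, n in DIVISION_COUNTS.items():
        for _ in range(n):
            rows.append({
                "trainer_gender": next(cyc["trainer_gender"]),
                "time_bin": next(cyc["time_bin"]),
                "day_of_week": next(cyc["day_of_week"]),
                "month": next(cyc["month"]),
                "venue": next(cyc["venue"]),
                "division": division,
                "males": str(int(rng.integers(4, 600))),
                "females": str(int(rng.integers(0, 150))),
            })
    for i in range(N_EXCLUDED):
        bad = dict(rows[i])
        bad["females"] = ""  # missing count information
        rows.append(bad)
    return pd.DataFrame(rows, columns=list(COLUMNS))


@pytest.fixture(scope="session")
def study_raw_frame() -> pd.DataFrame:
    return _study_raw_frame()


@pytest.fixture(scope="session")
def study_table(study_raw_frame):
    return events_from_frame(study_raw_frame)


@pytest.fixture(scope="session")
def study_csv(tmp_path_factory, study_raw_frame):
    path = tmp_path_factory.mktemp("data") / "events.csv"
    study_raw_frame.to_csv(path, index=False)
    return path


def make_table(rows: list[dict]):
    """Build a validated EventTable from partial row dicts (defaults fill
    the remaining fields)."""
    base = {"trainer_gender": "male", "time_bin": "before_11",
            "day_of_week": "sunday", "month": "oct2018",
            "venue": "farmers_house", "division": "rangpur",
            "males": 10, "females": 5}
    frame = pd.DataFrame([{**base, **r} for r in rows], columns=list(COLUMNS))
    return events_from_frame(frame.astype(str))
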