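"""Shared fixtures: study-table files, hand-built scan data, simulations."""

from __future__ import annotations

import io
from datetime import date, datetime, timedelta

import pandas as pd
import pytest

from groomnet import reference_tables
from groomnet.study_data import (ObservationPeriod, ScanRecord, read_periods,
                                 read_roster)


@pytest.fixture(scope="session")
def study_roster_file(tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("tables") / "roster.csv"
    path.write_text(reference_tables.ROSTER_CSV)
    return str(path)


@pytest.fixture(scope="session")
def study_periods_file(tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("tables") / "periods.csv"
    path.write_text(reference_tables.PERIODS_CSV)
    return str(path)


@pytest.fixture(scope="session")
def study_roster(study_roster_file):
    return read_roster(study_roster_file)


@pytest.fixture(scope="session")
def study_periods(study_roster_file, study_periods_file, study_roster):
    return read_periods(study_periods_file, roster=study_roster)


@pytest.fixture
def small_period() -> ObservationPeriod:
    return ObservationPeriod(
        code="T1", group="G", members=frozenset({"A", "B", "C"}),
        start_date=date(2020, 1, 1), end_date=date(2020, 7, 1),
        stability="stable")


def make_scans(period: ObservationPeriod, n_scans: int,
               events_by_scan: dict[int, set[tuple[str, str]]] | None = None,
               spread_weeks: bool = True) -> list[ScanRecord]:
    """Scans with all members present, sessions spread over the period.

    Sessions are 10-scan (20-minute) blocks alternating morning and
    afternoon starts; with ``spread_weeks`` the session days cover the full
    date span, otherwise everything lands in the first week.
    """
    events_by_scan = events_by_scan or {}
    span_days = (period.end_date - period.start_date).days
    n_sessions = -(-n_scans // 10)
    records = []
    for s in range(n_scans):
        session = s // 10
        if spread_weeks and n_sessions > 1:
            day = round(session * (span_days - 1) / (n_sessions - 1))
        else:
            day = session % 5
        start_minute = (11 * 60) if session % 2 == 0 else (16 * 60)
        minute = start_minute + 2 * (s % 10)
        ts = (datetime.combine(period.start_date, datetime.min.time())
              + timedelta(days=day, minutes=minute))
        records.append(ScanRecord(
            scan_id=s, period_code=period.code, timestamp=ts,
            present=frozenset(period.members),
            grooming_events=frozenset(events_by_scan.get(s, set()))))
    return records


@pytest.fixture
def scans_csv_text() -> str:
    """Three rows, one scan, one grooming event (A grooms B; C idle)."""
    return (
        "scan_id,period_code,timestamp,individual,grooming_recipient\n"
        "1,T1,2020-01-02 11:00,A,B\n"
        "1,T1,2020-01-02 11:00,B,\n"
        "1,T1,2020-01-02 11:00,C,\n")


def csv_buffer(text: str) -> io.StringIO:
    return io.StringIO(text)
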