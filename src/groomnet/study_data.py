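"""Domain types, CSV I/O, period classification and dyadic counting.

The observational unit is an instantaneous scan: every two minutes each
individual present in the outdoor enclosure is scored once, and "social
grooming given" is the only behavior carried through this pipeline. Scans
aggregate into directed dyad counts per observation time period; a period
is an interval of fixed group composition labelled stable (no composition
change for at least four months) or unstable.

File dialects (UTF-8, comma-separated, header row required):

* ``roster.csv``  — ``id,sex,origin,phc_infant,arrival_age_cat``
* ``periods.csv`` — ``code,group,start_date,end_date,stability,members``
  (members ``;``-delimited within the cell; ``,`` also accepted)
* ``scans.csv``   — ``scan_id,period_code,timestamp,individual,
  grooming_recipient`` with one row per present individual and an empty
  recipient when the individual was not grooming.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("groomnet")

# Enum domains for the five fixed factors (stability lives on the period).
SEX_LEVELS = ("F", "M")
ORIGIN_LEVELS = ("wild", "captive")
PHC_LEVELS = ("with_conspecifics", "without_conspecifics")
ARRIVAL_LEVELS = ("subadult", "adult")
STABILITY_LEVELS = ("stable", "unstable")
EVENT_KINDS = ("addition", "removal", "shuffle")

_PHC_ALIASES = {"with": "with_conspecifics", "without": "without_conspecifics"}
_ARRIVAL_ALIASES = {"sub-adult": "subadult", "sub_adult": "subadult"}


class ValidationError(ValueError):
    """Raised when an input file or record violates a domain invariant."""


def _parse_enum(value: object, levels: Sequence[str], field_name: str,
                row: object, aliases: dict[str, str] | None = None) -> str:
    text = str(value).strip().lower()
    if aliases and text in aliases:
        text = aliases[text]
    for level in levels:
        if text == level.lower():
            return level
    raise ValidationError(
        f"row {row}: field '{field_name}' has value {value!r}, "
        f"expected one of {list(levels)}"
    )


@dataclass(frozen=True)
class Individual:
    """One study subject with the four subject-level binary covariates."""

    id: str
    sex: str
    origin: str
    phc_infant: str
    arrival_age_cat: str


@dataclass(frozen=True)
class ObservationPeriod:
    """A (group, composition, date span, stability) observation unit."""

    code: str
    group: str
    members: frozenset[str]
    start_date: date
    end_date: date  # half-open: [start_date, end_date)
    stability: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError(
                f"period {self.code}: {len(self.members)} member(s); a "
                "grooming network needs at least 2"
            )
        if not self.start_date < self.end_date:
            raise ValidationError(
                f"period {self.code}: start_date {self.start_date} must "
                f"precede end_date {self.end_date}"
            )

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ScanRecord:
    """One instantaneous scan: who was present and who groomed whom.

    Each present individual is scored exactly once per scan, so an actor
    appears in at most one grooming event.
    """

    scan_id: int
    period_code: str
    timestamp: datetime
    present: frozenset[str]
    grooming_events: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        actors = [a for a, _ in self.grooming_events]
        if len(actors) != len(set(actors)):
            raise ValidationError(
                f"scan {self.scan_id}: an actor has more than one grooming "
                "event; one scored behavior per individual per scan"
            )
        for actor, recipient in self.grooming_events:
            if actor == recipient:
                raise ValidationError(
                    f"scan {self.scan_id}: {actor} grooming itself")
            if actor not in self.present or recipient not in self.present:
                raise ValidationError(
                    f"scan {self.scan_id}: grooming pair ({actor}, "
                    f"{recipient}) not contained in the present set"
                )


@dataclass(frozen=True)
class DyadCount:
    """Scan counts for one ordered pair within one period."""

    period_code: str
    actor: str
    recipient: str
    groom_scans: int
    copresent_scans: int

    def __post_init__(self) -> None:
        if self.actor == self.recipient:
            raise ValidationError("dyad actor equals recipient")
        if not 0 <= self.groom_scans <= self.copresent_scans:
            raise ValidationError(
                f"dyad {self.actor}->{self.recipient}: groom_scans "
                f"{self.groom_scans} outside [0, {self.copresent_scans}]"
            )


@dataclass(frozen=True)
class CompositionEvent:
    """A permanent or short-term alteration of a group's composition."""

    group: str
    date: date
    kind: str
    individuals: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if not self.individuals:
            raise ValidationError("composition event with no individuals")


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

ROSTER_COLUMNS = ["id", "sex", "origin", "phc_infant", "arrival_age_cat"]
PERIOD_COLUMNS = ["code", "group", "start_date", "end_date", "stability",
                  "members"]
SCAN_COLUMNS = ["scan_id", "period_code", "timestamp", "individual",
                "grooming_recipient"]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return frame


def read_roster(path: str | Path) -> list[Individual]:
    """Read a roster.csv into validated :class:`Individual` records."""
    frame = _read_csv(path, ROSTER_COLUMNS)
    roster: list[Individual] = []
    seen: set[str] = set()
    for row_idx, row in frame.iterrows():
        ind_id = str(row["id"]).strip()
        if not ind_id:
            raise ValidationError(f"row {row_idx}: empty id")
        if ind_id in seen:
            raise ValidationError(f"row {row_idx}: duplicate id {ind_id!r}")
        seen.add(ind_id)
        roster.append(Individual(
            id=ind_id,
            sex=_parse_enum(row["sex"], SEX_LEVELS, "sex", row_idx),
            origin=_parse_enum(row["origin"], ORIGIN_LEVELS, "origin",
                               row_idx),
            phc_infant=_parse_enum(row["phc_infant"], PHC_LEVELS,
                                   "phc_infant", row_idx, _PHC_ALIASES),
            arrival_age_cat=_parse_enum(row["arrival_age_cat"],
                                        ARRIVAL_LEVELS, "arrival_age_cat",
                                        row_idx, _ARRIVAL_ALIASES),
        ))
    return roster


def _parse_date(value: object, field_name: str, row: object) -> date:
    try:
        return date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValidationError(
            f"row {row}: field '{field_name}' is not an ISO date: {value!r}"
        ) from exc


def read_periods(path: str | Path,
                 roster: Sequence[Individual] | None = None,
                 ) -> list[ObservationPeriod]:
    """Read periods.csv, optionally validating member ids against a roster.

    Output is sorted chronologically within group (group, start_date, code).
    """
    frame = _read_csv(path, PERIOD_COLUMNS)
    known = {ind.id for ind in roster} if roster is not None else None
    periods: list[ObservationPeriod] = []
    seen: set[str] = set()
    for row_idx, row in frame.iterrows():
        code = str(row["code"]).strip()
        if code in seen:
            raise ValidationError(f"row {row_idx}: duplicate period code "
                                  f"{code!r}")
        seen.add(code)
        raw = str(row["members"]).replace(",", ";")
        members = frozenset(m.strip() for m in raw.split(";") if m.strip())
        if known is not None:
            unknown = members - known
            if unknown:
                raise ValidationError(
                    f"period {code}: member(s) {sorted(unknown)} absent "
                    "from roster"
                )
        periods.append(ObservationPeriod(
            code=code,
            group=str(row["group"]).strip(),
            members=members,
            start_date=_parse_date(row["start_date"], "start_date", row_idx),
            end_date=_parse_date(row["end_date"], "end_date", row_idx),
            stability=_parse_enum(row["stability"], STABILITY_LEVELS,
                                  "stability", row_idx),
        ))
    periods.sort(key=lambda p: (p.group, p.start_date, p.code))
    return periods


def read_scans(path: str | Path,
               periods: Sequence[ObservationPeriod] | None = None,
               ) -> list[ScanRecord]:
    """Read scans.csv (one row per present individual) into ScanRecords."""
    frame = _read_csv(path, SCAN_COLUMNS)
    by_period = {p.code: p for p in periods} if periods is not None else None
    # manual grouping: scans files run to hundreds of thousands of rows
    grouped: dict[tuple[int, str], list[tuple[str, str, str]]] = {}
    for row in frame.itertuples(index=False):
        key = (int(row.scan_id), str(row.period_code))
        grouped.setdefault(key, []).append(
            (str(row.individual).strip(), str(row.grooming_recipient).strip(),
             str(row.timestamp)))
    records: list[ScanRecord] = []
    for (scan_id, period_code), rows in sorted(grouped.items()):
        present = [ind for ind, _, _ in rows]
        if len(present) != len(set(present)):
            dupes = sorted({i for i in present if present.count(i) > 1})
            raise ValidationError(
                f"scan {scan_id}: duplicate row(s) for individual(s) {dupes}"
            )
        events = frozenset(
            (ind, rec) for ind, rec, _ in rows if rec)
        record = ScanRecord(
            scan_id=scan_id,
            period_code=period_code,
            timestamp=pd.Timestamp(rows[0][2]).to_pydatetime(),
            present=frozenset(present),
            grooming_events=events,
        )
        if by_period is not None:
            period = by_period.get(record.period_code)
            if period is None:
                raise ValidationError(
                    f"scan {scan_id}: unknown period {record.period_code!r}")
            stray = record.present - period.members
            if stray:
                raise ValidationError(
                    f"scan {scan_id}: individual(s) {sorted(stray)} not in "
                    f"period {period.code} membership"
                )
        records.append(record)
    records.sort(key=lambda r: r.scan_id)
    return records


# ---------------------------------------------------------------------------
# Period classification
# ---------------------------------------------------------------------------

def _add_months(day: date, months: int) -> date:
    month_index = day.month - 1 + months
    year = day.year + month_index // 12
    month = month_index % 12 + 1
    return date(year, month, min(day.day, calendar.monthrange(year, month)[1]))


def classify_periods(events: Iterable[CompositionEvent],
                     span: tuple[date, date],
                     min_stable_months: int = 4,
                     ) -> list[tuple[tuple[date, date], str]]:
    """Partition a date span into stable/unstable intervals.

    Each composition event opens an unstable window of ``min_stable_months``
    starting at the event; overlapping windows merge. The quiet gaps between
    windows are stable only if they last at least ``min_stable_months``,
    otherwise they remain unstable (too short to re-qualify). Intervals are
    half-open and tile the span exactly.
    """
    start, end = span
    if not start < end:
        raise ValidationError(f"empty span: [{start}, {end})")
    windows: list[tuple[date, date]] = []
    for event in sorted(events, key=lambda e: e.date):
        if event.date >= end or _add_months(event.date, min_stable_months) <= start:
            continue
        w_start = max(event.date, start)
        w_end = min(_add_months(event.date, min_stable_months), end)
        if windows and w_start <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], w_end))
        else:
            windows.append((w_start, w_end))

    intervals: list[tuple[tuple[date, date], str]] = []
    cursor = start
    for w_start, w_end in windows:
        if cursor < w_start:
            gap = (cursor, w_start)
            label = ("stable" if _add_months(gap[0], min_stable_months)
                     <= gap[1] else "unstable")
            intervals.append((gap, label))
        intervals.append(((w_start, w_end), "unstable"))
        cursor = w_end
    if cursor < end:
        gap = (cursor, end)
        label = ("stable" if _add_months(gap[0], min_stable_months) <= gap[1]
                 else "unstable")
        intervals.append((gap, label))
    return intervals


def reconcile_stability(period: ObservationPeriod,
                        computed: str) -> str:
    """Prefer a supplied stability label over a classifier-derived one.

    Used when periods carry labels (table mode) and composition events are
    also available: the supplied label wins, with a warning on disagreement.
    """
    if period.stability != computed:
        logger.warning(
            "period %s: supplied stability %r disagrees with classified %r; "
            "keeping the supplied label", period.code, period.stability,
            computed)
    return period.stability


# ---------------------------------------------------------------------------
# Dyadic counting and data-sufficiency filters
# ---------------------------------------------------------------------------

def count_dyads(scans: Sequence[ScanRecord],
                period: ObservationPeriod) -> list[DyadCount]:
    """Count grooming and co-presence scans for every ordered member pair.

    Co-presence means joint membership in a scan's present set; it is the
    denominator of the percent grooming weight. Pairs never co-present get
    ``copresent_scans = 0``.
    """
    members = sorted(period.members)
    copresent: dict[tuple[str, str], int] = {}
    groomed: dict[tuple[str, str], int] = {}
    for scan in scans:
        if scan.period_code != period.code:
            raise ValidationError(
                f"scan {scan.scan_id} belongs to period {scan.period_code}, "
                f"not {period.code}"
            )
        stray = scan.present - period.members
        if stray:
            raise ValidationError(
                f"scan {scan.scan_id}: individual(s) {sorted(stray)} not in "
                f"period {period.code} membership"
            )
        present = sorted(scan.present)
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                copresent[(a, b)] = copresent.get((a, b), 0) + 1
        for actor, recipient in scan.grooming_events:
            key = (actor, recipient)
            groomed[key] = groomed.get(key, 0) + 1

    counts: list[DyadCount] = []
    for a in members:
        for b in members:
            if a == b:
                continue
            co = copresent.get((min(a, b), max(a, b)), 0)
            counts.append(DyadCount(
                period_code=period.code, actor=a, recipient=b,
                groom_scans=groomed.get((a, b), 0), copresent_scans=co,
            ))
    return counts


@dataclass(frozen=True)
class EvennessRule:
    """Session-spread rule standing in for 'evenly distributed sessions'.

    Sessions are 20-minute observation blocks inferred from scan timestamps.
    A period passes when sessions cover at least ``min_week_coverage`` of its
    calendar weeks and the morning-session fraction (session start before
    ``afternoon_cutoff_hour``) lies inside ``morning_fraction_range``.
    """

    min_week_coverage: float = 0.5
    morning_fraction_range: tuple[float, float] = (0.35, 0.65)
    afternoon_cutoff_hour: int = 14
    session_minutes: int = 20

    def check(self, scans: Sequence[ScanRecord],
              period: ObservationPeriod) -> list[str]:
        """Return the list of failed-rule names (empty when passing)."""
        sessions = {
            (s.timestamp.date(),
             (s.timestamp.hour * 60 + s.timestamp.minute)
             // self.session_minutes)
            for s in scans
        }
        failures: list[str] = []
        weeks_covered = {day.isocalendar()[:2] for day, _ in sessions}
        total_weeks = max(
            1, (period.end_date - period.start_date).days // 7)
        if len(weeks_covered) / total_weeks < self.min_week_coverage:
            failures.append("week_coverage")
        n_morning = sum(
            1 for _, block in sessions
            if block * self.session_minutes
            < self.afternoon_cutoff_hour * 60)
        lo, hi = self.morning_fraction_range
        if sessions and not lo <= n_morning / len(sessions) <= hi:
            failures.append("morning_balance")
        return failures


def apply_period_filters(
    scans: Sequence[ScanRecord],
    periods: Sequence[ObservationPeriod],
    min_scans_per_individual: int = 480,
    evenness: EvennessRule | None = EvennessRule(),
) -> tuple[list[ObservationPeriod], pd.DataFrame]:
    """Apply the data-sufficiency filters and report exclusions.

    A period is retained iff every member appears in at least
    ``min_scans_per_individual`` scans (the study cutoff, 480 scans = 16 h
    of observation) and the evenness rule passes. The report has columns
    ``period_code, individual, reason``; the individual column is empty for
    period-level (evenness) exclusions.
    """
    by_period: dict[str, list[ScanRecord]] = {p.code: [] for p in periods}
    for scan in scans:
        if scan.period_code in by_period:
            by_period[scan.period_code].append(scan)

    retained: list[ObservationPeriod] = []
    rows: list[dict[str, str]] = []
    for period in periods:
        period_scans = by_period[period.code]
        failures: list[dict[str, str]] = []
        for member in sorted(period.members):
            n_scans = sum(1 for s in period_scans if member in s.present)
            if n_scans < min_scans_per_individual:
                failures.append({"period_code": period.code,
                                 "individual": member,
                                 "reason": "min_scans"})
        if evenness is not None:
            for rule in evenness.check(period_scans, period):
                failures.append({"period_code": period.code,
                                 "individual": "", "reason": rule})
        if failures:
            rows.extend(failures)
        else:
            retained.append(period)
    report = pd.DataFrame(rows, columns=["period_code", "individual",
                                         "reason"])
    return retained, report
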