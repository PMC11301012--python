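"""Home blood pressure (HBP) measurement streams and per-period 14-day averages.

Participants self-measure blood pressure at home for 14 days. Each reading is
assigned to one of three day periods — morning, midday/afternoon, evening —
where the evening period wraps past midnight into the early hours of the next
calendar day. Within each (logical day, period) cell only the first reading
counts; the retained readings are averaged per period over the whole window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PERIODS = ("morning", "midday", "evening")

#: Half-open clock windows. Evening spans 16:00-28:00, i.e. readings taken
#: between midnight and 04:00 belong to the evening of the previous day.
MORNING_START = time(4, 0)
MIDDAY_START = time(11, 0)
EVENING_START = time(16, 0)


@dataclass(frozen=True)
class BPMeasurement:
    """One timestamped systolic/diastolic reading for a participant.

    Pressures are in mmHg; systolic must exceed diastolic and both must be
    positive.
    """

    participant_id: str
    timestamp: datetime
    sbp: int
    dbp: int

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise ValueError(
                f"require sbp > dbp > 0, got sbp={self.sbp}, dbp={self.dbp}"
            )


@dataclass(frozen=True)
class PeriodAverage:
    """Per-period mean blood pressure over the monitoring window.

    ``mean_sbp``/``mean_dbp`` are ``None`` when no measurement contributed
    (``n_used == 0``).
    """

    participant_id: str
    period: str
    n_used: int
    mean_sbp: float | None
    mean_dbp: float | None


def assign_period(timestamp: datetime) -> tuple[str, date]:
    """Map a clock timestamp to its day period and logical day.

    Windows are half-open: morning [04:00, 11:00), midday [11:00, 16:00),
    evening [16:00, 04:00 next day). A reading at 02:00 is the evening of
    the previous calendar day.
    """
    t = timestamp.time()
    d = timestamp.date()
    if t < MORNING_START:
        return "evening", d - timedelta(days=1)
    if t < MIDDAY_START:
        return "morning", d
    if t < EVENING_START:
        return "midday", d
    return "evening", d


def dedup_first_per_period(
    measurements: Sequence[BPMeasurement],
) -> list[BPMeasurement]:
    """Keep only the first reading in each (logical day, period) cell.

    "First" is earliest by timestamp; ties on identical timestamps keep the
    earlier input row and log a warning. Output is chronological. Idempotent.
    """
    indexed = sorted(
        enumerate(measurements), key=lambda pair: (pair[1].timestamp, pair[0])
    )
    kept: dict[tuple[date, str], BPMeasurement] = {}
    for _, m in indexed:
        period, day = assign_period(m.timestamp)
        cell = (day, period)
        if cell in kept:
            if kept[cell].timestamp == m.timestamp:
                logger.warning(
                    "duplicate timestamp %s for participant %s in %s cell; "
                    "keeping first input row",
                    m.timestamp,
                    m.participant_id,
                    period,
                )
            continue
        kept[cell] = m
    return sorted(kept.values(), key=lambda m: m.timestamp)


def filter_window(
    measurements: Iterable[BPMeasurement],
    start: date,
    days: int = 14,
) -> list[BPMeasurement]:
    """Drop readings whose logical day falls outside [start, start + days).

    Out-of-window readings are logged and discarded; the protocol does not
    define behaviour for late readings, so they never enter the averages.
    """
    end = start + timedelta(days=days)
    kept = []
    for m in measurements:
        _, day = assign_period(m.timestamp)
        if start <= day < end:
            kept.append(m)
        else:
            logger.warning(
                "dropping out-of-window reading at %s for participant %s "
                "(window %s..%s)",
                m.timestamp,
                m.participant_id,
                start,
                end,
            )
    return kept


def period_averages(
    measurements: Sequence[BPMeasurement],
    dedup: bool = True,
) -> list[PeriodAverage]:
    """Arithmetic mean systolic/diastolic per day period.

    Returns one record per period (morning, midday, evening), with
    ``n_used = 0`` and absent means for periods without readings. Applies
    :func:`dedup_first_per_period` first unless ``dedup=False`` (input
    already reduced).
    """
    if dedup:
        measurements = dedup_first_per_period(measurements)
    pid = measurements[0].participant_id if measurements else ""
    by_period: dict[str, list[BPMeasurement]] = {p: [] for p in PERIODS}
    for m in measurements:
        period, _ = assign_period(m.timestamp)
        by_period[period].append(m)
    out = []
    for period in PERIODS:
        group = by_period[period]
        if group:
            out.append(
                PeriodAverage(
                    participant_id=pid,
                    period=period,
                    n_used=len(group),
                    mean_sbp=sum(m.sbp for m in group) / len(group),
                    mean_dbp=sum(m.dbp for m in group) / len(group),
                )
            )
        else:
            out.append(PeriodAverage(pid, period, 0, None, None))
    return out


# ---------------------------------------------------------------------------
# CSV interfaces


def read_measurements_csv(path) -> list[BPMeasurement]:
    """Read a measurements CSV (participant_id,timestamp,sbp,dbp)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "timestamp", "sbp", "dbp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurements CSV missing columns: {sorted(missing)}")
    return [
        BPMeasurement(
            participant_id=row.participant_id,
            timestamp=datetime.fromisoformat(row.timestamp),
            sbp=int(row.sbp),
            dbp=int(row.dbp),
        )
        for row in df.itertuples()
    ]


def averages_frame(measurements: Sequence[BPMeasurement]) -> pd.DataFrame:
    """Per-participant period averages as a tidy frame.

    Columns: participant_id, period, n_used, mean_sbp, mean_dbp. Participants
    are ordered by id, periods in morning/midday/evening order.
    """
    by_pid: dict[str, list[BPMeasurement]] = {}
    for m in measurements:
        by_pid.setdefault(m.participant_id, []).append(m)
    rows = []
    for pid in sorted(by_pid):
        for avg in period_averages(by_pid[pid]):
            rows.append(
                {
                    "participant_id": pid,
                    "period": avg.period,
                    "n_used": avg.n_used,
                    "mean_sbp": avg.mean_sbp,
                    "mean_dbp": avg.mean_dbp,
                }
            )
    return pd.DataFrame(
        rows, columns=["participant_id", "period", "n_used", "mean_sbp", "mean_dbp"]
    )
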