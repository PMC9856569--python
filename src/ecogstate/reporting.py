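"""Interval summaries and feature-trace correlation tables.

Summaries follow the wall clock: named intervals are given as "HH:MM"
clock times resolved against the recording start (an end time at or before
the start clock time is taken to wrap past midnight), and every window is
additionally labelled day (08:00-20:00) or night.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ConsciousnessTrace, FeatureMatrix

__all__ = [
    "Interval",
    "resolve_intervals",
    "summarize",
    "percent_clear_answers",
    "day_night_means",
    "feature_correlations",
]

DAY_START = time(8, 0)
DAY_END = time(20, 0)


@dataclass(frozen=True)
class Interval:
    name: str
    start: datetime
    end: datetime


def _parse_clock(s: str) -> time:
    h, m = s.split(":")
    return time(int(h), int(m))


def resolve_intervals(
    named: dict[str, tuple[str, str]], reference: datetime
) -> list[Interval]:
    """Resolve {"name": ("HH:MM", "HH:MM")} against the recording start.

    Each clock time maps to the first occurrence at or after ``reference``;
    the end wraps to the next day when it does not follow the start.
    """
    out = []
    for name, (s, e) in named.items():
        st, et = _parse_clock(s), _parse_clock(e)
        start = datetime.combine(reference.date(), st)
        if start < reference:
            start += timedelta(days=1)
        end = datetime.combine(start.date(), et)
        if end <= start:
            end += timedelta(days=1)
        out.append(Interval(name, start, end))
    return out


def _is_day(t: datetime) -> bool:
    return DAY_START <= t.time() < DAY_END


def day_night_means(trace: ConsciousnessTrace) -> dict[str, float]:
    day = np.array([_is_day(t) for t in trace.times])
    out: dict[str, float] = {}
    out["day"] = float(trace.values[day].mean()) if day.any() else float("nan")
    out["night"] = float(trace.values[~day].mean()) if (~day).any() else float("nan")
    return out


def summarize(
    trace: ConsciousnessTrace,
    intervals: list[Interval] | None = None,
    clear_answers: int | None = None,
    total_questions: int | None = None,
) -> dict:
    """Mean trace value per named interval plus day/night means.

    Empty intervals are reported as None (missing), never silently as 0.
    When answer counts are supplied the clear-answer percentage is included.
    """
    summary: dict = {
        "overall_mean": float(trace.values.mean()),
        "day_night": day_night_means(trace),
        "intervals": {},
    }
    times = np.array(trace.times)
    for iv in intervals or []:
        mask = (times >= iv.start) & (times < iv.end)
        summary["intervals"][iv.name] = (
            float(trace.values[mask].mean()) if mask.any() else None
        )
    if clear_answers is not None and total_questions is not None:
        summary["clear_answer_rate_percent"] = percent_clear_answers(
            clear_answers, total_questions
        )
    return summary


def percent_clear_answers(clear: int, total: int) -> float:
    """Clear-answer rate as a percentage (e.g. 16 of 18 -> 88.89)."""
    if total <= 0:
        raise ValueError("total question count must be positive")
    if not (0 <= clear <= total):
        raise ValueError(f"clear answers {clear} outside [0, {total}]")
    return round(100.0 * clear / total, 2)


def feature_correlations(
    F: FeatureMatrix, traces: dict[str, ConsciousnessTrace]
) -> pd.DataFrame:
    """Spearman rank correlation of every feature against every trace.

    Returns a DataFrame indexed by feature with a (rho, p) column pair per
    trace.  Constant columns yield NaN (flagged by a warning from scipy),
    never a silent zero.
    """
    rows = {}
    for j, name in enumerate(F.names):
        row = {}
        for tname, tr in traces.items():
            if len(tr.values) != F.n_windows:
                raise ValueError(f"trace {tname!r} is not aligned with the features")
            rho, p = stats.spearmanr(F.raw[:, j], tr.values)
            row[(tname, "rho")] = rho
            row[(tname, "p")] = p
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df
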