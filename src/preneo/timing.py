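"""Timing of persistent CNA events across longitudinal profiles.

An event observed in a time series of copy-number profiles is *persistent*
if it is present at the final sampled day; its time of appearance is the
earliest sampled day from which it stays present through the end (a strict
suffix, with an optional tolerance for isolated missed calls at intermediate
time points — shallow coverage can drop an event below threshold once).
Events that appeared but are absent at the final day are flagged extinct and
excluded from timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .cna import CopyNumberProfile, compute_fga

__all__ = ["EventTimeline", "build_timeline", "summarize_order", "fga_trajectory"]


@dataclass
class EventTimeline:
    culture_id: str
    event_id: str
    presence: list[tuple[int, bool]]
    persistent: bool
    extinct: bool
    time_of_appearance: int | None


def _check_days(days: list[int]) -> None:
    if len(days) < 2:
        raise ValueError("need at least two time points")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing without duplicates")


def build_timeline(
    profiles: list[CopyNumberProfile],
    event_id: str,
    culture_id: str = "",
    tolerance: int = 0,
) -> EventTimeline:
    """Presence/persistence timeline of one event over time-ordered profiles.

    ``tolerance`` allows up to that many absent intermediate calls inside the
    persistent suffix (default 0: a single missed call breaks the suffix).
    """
    days = [p.day for p in profiles]
    _check_days(days)
    present = [event_id in p.present_events() for p in profiles]
    presence = list(zip(days, present))

    persistent = present[-1]
    ever = any(present)
    extinct = ever and not persistent
    appearance: int | None = None
    if persistent:
        # earliest present day whose suffix has ≤ tolerance absences
        for i in range(len(days)):
            if not present[i]:
                continue
            absences = sum(1 for b in present[i:] if not b)
            if absences <= tolerance:
                appearance = days[i]
                break
    return EventTimeline(
        culture_id=culture_id,
        event_id=event_id,
        presence=presence,
        persistent=persistent,
        extinct=extinct,
        time_of_appearance=appearance,
    )


def build_timelines(
    profiles: list[CopyNumberProfile], culture_id: str = "", tolerance: int = 0
) -> list[EventTimeline]:
    """Timelines for every event observed at any time point."""
    events = sorted(set().union(*(p.present_events() for p in profiles)))
    return [build_timeline(profiles, e, culture_id, tolerance) for e in events]


def summarize_order(timelines: list[EventTimeline]) -> pd.DataFrame:
    """Per-event appearance-day summary over cultures, ordered by median day.

    Only persistent timelines contribute. Columns: event_id, n_cultures,
    median_day, iqr, rank (1 = earliest median).
    """
    rows: dict[str, list[int]] = {}
    for tl in timelines:
        if tl.persistent and tl.time_of_appearance is not None:
            rows.setdefault(tl.event_id, []).append(tl.time_of_appearance)
    out = []
    for event_id, days in rows.items():
        q1, med, q3 = np.percentile(days, [25, 50, 75])
        out.append(
            {
                "event_id": event_id,
                "n_cultures": len(days),
                "median_day": float(med),
                "iqr": float(q3 - q1),
            }
        )
    df = pd.DataFrame(out, columns=["event_id", "n_cultures", "median_day", "iqr"])
    df = df.sort_values(["median_day", "event_id"]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def fga_trajectory(
    profiles: list[CopyNumberProfile], plateau_fraction: float = 0.1
) -> tuple[pd.DataFrame, int]:
    """FGA per time point plus the plateau day of its monotone trend.

    The trend is an isotonic (non-decreasing) fit; the plateau day is the
    first sampled day after which the fitted trend rises by less than
    ``plateau_fraction`` of its total range.
    """
    days = [p.day for p in profiles]
    if len(days) < 3:
        raise ValueError("need at least three time points")
    _check_days(days)
    fga = np.array([compute_fga(p) for p in profiles])
    fitted = IsotonicRegression(increasing=True).fit_transform(days, fga)
    rng = fitted[-1] - fitted[0]
    if rng <= 0:
        plateau = days[0]
    else:
        plateau = days[-1]
        for d, f in zip(days, fitted):
            if fitted[-1] - f < plateau_fraction * rng:
                plateau = d
                break
    table = pd.DataFrame({"day": days, "fga": fga, "fga_trend": fitted})
    return table, int(plateau)
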