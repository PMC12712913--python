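"""Behavioral scoring from pre-scored event tables.

Inputs are tidy event tables (CSV: ``label,start_s,stop_s``) produced by a
tracking system; scoring reduces them to the standard summary measures:

* Y-maze spontaneous alternation: percent of consecutive arm-entry triplets
  visiting three distinct arms, ``100 x alternations / (entries - 2)``;
* forced-swim immobility: bout count and total immobile time within a scoring
  window (by convention the last 4 minutes of a 6-minute test, 120–360 s);
* open-field / elevated-plus-maze zone summaries: entry counts and cumulative
  time per zone, overlapping bouts merged first.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_event_table",
    "alternation_percentage",
    "immobility_summary",
    "zone_summary",
]


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a ``label,start_s,stop_s`` event table."""
    df = pd.read_csv(path)
    return validate_event_table(df)


def validate_event_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = {"label", "start_s", "stop_s"} - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    if (df["start_s"] < 0).any() or (df["stop_s"] < df["start_s"]).any():
        raise ValueError("event times must be non-negative with start <= stop")
    return df


def alternation_percentage(entries: list[str]) -> float:
    """Spontaneous alternation percent from an arm-entry sequence.

    An alternation is a window of three consecutive entries into three
    distinct arms; the score is ``100 x alternations / (n - 2)``.
    """
    if len(entries) < 3:
        raise ValueError("need at least 3 arm entries")
    wins = [entries[i : i + 3] for i in range(len(entries) - 2)]
    count = sum(len(set(w)) == 3 for w in wins)
    return 100.0 * count / (len(entries) - 2)


def _bouts(df: pd.DataFrame, label: str) -> np.ndarray:
    sel = df[df["label"] == label]
    return sel[["start_s", "stop_s"]].to_numpy(dtype=float)


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Union of possibly overlapping [start, stop] intervals."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].copy()]
    for start, stop in iv[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append(np.array([start, stop]))
    return np.vstack(merged)


def immobility_summary(
    events: pd.DataFrame,
    window: tuple[float, float] = (120.0, 360.0),
    label: str = "immobile",
) -> tuple[int, float]:
    """Immobility bout count and total duration (s) within the scoring window.

    Bouts are clipped to the window; bouts falling entirely outside are
    dropped.
    """
    validate_event_table(events)
    lo, hi = window
    bouts = _bouts(events, label)
    clipped = []
    for start, stop in bouts:
        s, e = max(start, lo), min(stop, hi)
        if e > s:
            clipped.append((s, e))
    total = float(sum(e - s for s, e in clipped))
    return len(clipped), total


def zone_summary(
    events: pd.DataFrame, zone: str
) -> tuple[int, float, float | None]:
    """Zone entries, cumulative time in zone (s), and mean speed when a
    ``distance_m`` column is present (total distance / total time).

    Overlapping bouts are merged before counting, so an entry is one maximal
    occupancy interval.
    """
    validate_event_table(events)
    bouts = _merge_intervals(_bouts(events, zone))
    time_in = float((bouts[:, 1] - bouts[:, 0]).sum()) if len(bouts) else 0.0
    speed = None
    if "distance_m" in events.columns:
        sel = events[events["label"] == zone]
        dist = float(sel["distance_m"].sum())
        speed = dist / time_in if time_in > 0 else None
    return len(bouts), time_in, speed
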