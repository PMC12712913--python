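"""Ultrasound-evoked potential (UEP) quantification.

The UEP is the stimulation-locked LFP deflection; its first negative trough
(N1) within 0–500 ms of ultrasound onset carries the response strength
(amplitude, µV) and timing (latency, ms). Detection is per trial: after an
optional short moving-average smoothing, the first local minimum whose depth
exceeds a significance floor (default three times the pre-onset standard
deviation) qualifies as N1. Trials without a qualifying trough are
non-responses: excluded from amplitude/latency means, reported as a rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .preprocess import (
    Epoch,
    EmptyEpochError,
    FilterSpec,
    apply_filters,
    baseline_correct,
    epoch,
    reject_artifacts,
)

__all__ = ["N1Result", "average_uep", "detect_n1", "uep_by_intensity", "summarize_uep"]


@dataclass
class N1Result:
    """Detected first negative deflection: trough magnitude and time."""

    amplitude: float  # µV, positive magnitude of the negative trough
    latency_ms: float  # ms after ultrasound onset


def average_uep(ep: Epoch) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SEM across kept trials."""
    kept = ep.kept()
    if kept.shape[0] == 0:
        raise EmptyEpochError("all trials rejected")
    mean = kept.mean(axis=0)
    n = kept.shape[0]
    sem = kept.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, sem


def _smooth(x: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    width = int(round(smooth_ms / 1000.0 * fs))
    if width <= 1:
        return x
    return uniform_filter1d(x, size=width, mode="nearest")


def detect_n1(
    trace: np.ndarray,
    fs: float,
    onset_index: int,
    search_ms: tuple[float, float] = (0.0, 500.0),
    smooth_ms: float = 5.0,
    floor_factor: float = 3.0,
    floor: float | None = None,
) -> N1Result | None:
    """First qualifying negative trough after stimulus onset.

    Parameters
    ----------
    trace : 1-D array
        Baseline-corrected trial (or trial-average) waveform, µV.
    onset_index : int
        Sample index of ultrasound onset within ``trace``.
    search_ms : (float, float)
        Search window in ms after onset.
    smooth_ms : float
        Moving-average width (ms); 0 disables smoothing.
    floor_factor, floor : float
        Significance floor in µV below which the trough must dip. By default
        ``floor_factor`` times the pre-onset SD of the (smoothed) trace; an
        explicit ``floor`` overrides this.

    Returns
    -------
    :class:`N1Result` or None when no trough qualifies (a non-response).

    The "first negative deflection" is the first contiguous excursion of the
    trace below the floor; its amplitude and latency are read at the
    excursion's minimum, so noise ripples within a single deflection do not
    truncate the measurement. With two separate qualifying troughs in-window,
    the earlier one is returned regardless of depth.
    """
    x = _smooth(np.asarray(trace, dtype=float).ravel(), fs, smooth_ms)
    if floor is None:
        if onset_index <= 1:
            raise ValueError("no pre-onset samples to estimate the noise floor from")
        floor = floor_factor * x[:onset_index].std()
    lo = onset_index + int(round(search_ms[0] / 1000.0 * fs))
    hi = onset_index + int(round(search_ms[1] / 1000.0 * fs))
    seg = x[lo : hi + 1]
    if seg.size < 3:
        raise ValueError("search window outside trace")
    below = seg <= -floor
    # zero floor (noiseless trace): fall back to the first strict local minimum
    if floor <= 0:
        minima, _ = sps.find_peaks(-seg)
        below = np.zeros_like(below)
        below[[m for m in minima if seg[m] < 0]] = True
    if not below.any():
        return None
    start = int(np.argmax(below))
    stop = start
    while stop + 1 < len(seg) and below[stop + 1]:
        stop += 1
    idx = start + int(np.argmin(seg[start : stop + 1]))
    return N1Result(
        amplitude=float(-seg[idx]),
        latency_ms=(lo + idx - onset_index) / fs * 1000.0,
    )


def uep_by_intensity(
    sessions: list[tuple["object", float]],
    fspec: FilterSpec | None = None,
    window: tuple[float, float] = (-1.0, 2.0),
    artifact: np.ndarray | None = None,
    rho_min: float = 0.8,
    search_ms: tuple[float, float] = (0.0, 500.0),
    smooth_ms: float = 5.0,
    floor_factor: float = 3.0,
) -> pd.DataFrame:
    """Per-trial N1 metrics across (Recording, intensity) sessions.

    Each session is filtered, epoched, baseline-corrected, optionally screened
    against an artifact template, and trough-detected trial by trial. Returns
    a tidy frame with one row per kept trial: ``subject``, ``intensity``,
    ``trial``, ``amplitude_uv``, ``latency_ms``, ``responded``.
    """
    rows = []
    for rec, intensity in sessions:
        clean = apply_filters(rec, fspec)
        ep = baseline_correct(epoch(clean, window), (window[0], 0.0))
        if artifact is not None:
            ep = reject_artifacts(ep, artifact, rho_min)
        subject = rec.meta.get("subject", "sim")
        for i in np.flatnonzero(ep.kept_mask):
            res = detect_n1(
                ep.data[i],
                ep.fs,
                ep.onset_index,
                search_ms=search_ms,
                smooth_ms=smooth_ms,
                floor_factor=floor_factor,
            )
            rows.append(
                {
                    "subject": subject,
                    "intensity": intensity,
                    "trial": int(i),
                    "amplitude_uv": res.amplitude if res else np.nan,
                    "latency_ms": res.latency_ms if res else np.nan,
                    "responded": res is not None,
                }
            )
    return pd.DataFrame(rows)


def summarize_uep(table: pd.DataFrame) -> pd.DataFrame:
    """Per-intensity summary: mean ± SEM amplitude and latency over responding
    trials, trial counts, and the non-response rate."""
    out = []
    for intensity, grp in table.groupby("intensity"):
        resp = grp[grp["responded"]]
        n = len(resp)
        out.append(
            {
                "intensity": intensity,
                "n_trials": len(grp),
                "n_responses": n,
                "nonresponse_rate": 1.0 - n / len(grp) if len(grp) else np.nan,
                "amplitude_mean_uv": resp["amplitude_uv"].mean() if n else np.nan,
                "amplitude_sem_uv": resp["amplitude_uv"].sem() if n > 1 else np.nan,
                "latency_mean_ms": resp["latency_ms"].mean() if n else np.nan,
                "latency_sem_ms": resp["latency_ms"].sem() if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(out).sort_values("intensity").reset_index(drop=True)
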