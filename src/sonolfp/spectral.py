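"""Welch spectra, band power, and stimulation-phase power statistics.

Band power is reported two ways, following common LFP practice:

* relative power (RP) per canonical band — the band's share of the total
  absolute power in the 0.5–100 Hz analysis range, in percent;
* total power in dB, ``10 log10(P_total / p_ref)`` with a configurable
  reference (default 1 µV²).

Phase statistics compare the stimulation phase against the pre-stimulation
baseline: ``(P_stim - P_pre) / P_pre x 100`` (percent change), with the same
quantity for the post phase as a recovery check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "CANONICAL_BANDS",
    "BandScheme",
    "BandPowerSummary",
    "PowerChange",
    "welch_psd",
    "band_powers",
    "phase_power_change",
    "spectrogram",
]

#: Canonical LFP bands (Hz): delta, theta, alpha, beta, gamma.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}


@dataclass
class BandScheme:
    """Contiguous, non-overlapping named frequency bands covering a total range."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CANONICAL_BANDS)
    )

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        for (lo, hi), (lo2, _) in zip(edges, edges[1:]):
            if hi > lo2:
                raise ValueError("bands overlap")
            if hi != lo2:
                raise ValueError("bands must be contiguous")
        for lo, hi in edges:
            if not lo < hi:
                raise ValueError("each band needs low < high")

    @property
    def total_range(self) -> tuple[float, float]:
        edges = sorted(self.bands.values())
        return edges[0][0], edges[-1][1]


@dataclass
class BandPowerSummary:
    """Total band-limited power (dB re p_ref) and relative power per band (%)."""

    total_power: float  # µV², absolute, over the total range
    total_power_db: float
    rp: dict[str, float]  # percent of total, sums to 100
    tg_ratio: float  # theta power / gamma power
    p_ref: float = 1.0


@dataclass
class PowerChange:
    """Per-phase total power and stimulation-normalized change statistics."""

    pre: float
    stim: float
    post: float
    change_pct: float  # (stim - pre) / pre * 100
    post_recovery_pct: float  # (post - pre) / pre * 100
    per_band: dict[str, "PowerChange"] | None = None


def welch_psd(
    x: np.ndarray,
    fs: float,
    seg_len: float = 2.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density (µV²/Hz), Hanning window.

    ``seg_len`` is the segment length in seconds (2 s gives 0.5 Hz resolution,
    matching the lower delta edge); ``overlap`` the fractional segment overlap.
    Density scaling, so integrating over frequency recovers the variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    nperseg = int(round(seg_len * fs))
    if nperseg < 2:
        raise ValueError("segment too short")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if len(x) < nperseg:
        raise ValueError(f"signal ({len(x)} samples) shorter than one segment ({nperseg})")
    return sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend="constant",
        scaling="density",
    )


def _integrate(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], interpolating both edges.

    Adjacent bands share the edge ordinate, so band integrals partition the
    total-range integral exactly.
    """
    inner = (freqs > lo) & (freqs < hi)
    fgrid = np.concatenate(([lo], freqs[inner], [hi]))
    pgrid = np.concatenate(
        ([np.interp(lo, freqs, psd)], psd[inner], [np.interp(hi, freqs, psd)])
    )
    return float(np.trapezoid(pgrid, fgrid))


def band_powers(
    freqs: np.ndarray,
    psd: np.ndarray,
    scheme: BandScheme | None = None,
    p_ref: float = 1.0,
) -> BandPowerSummary:
    """Absolute and relative band power from a PSD.

    RP per band is ``100 * P_band / P_total`` with the total taken over the
    scheme's full range; the theta/gamma power ratio is included when both
    bands are present.
    """
    scheme = BandScheme() if scheme is None else scheme
    lo_tot, hi_tot = scheme.total_range
    if freqs[0] > lo_tot or freqs[-1] < hi_tot:
        raise ValueError("PSD does not cover the scheme's total range")
    powers = {
        name: _integrate(freqs, psd, lo, hi) for name, (lo, hi) in scheme.bands.items()
    }
    total = sum(powers.values())
    if total <= 0:
        raise ValueError("total power is zero; relative power undefined")
    rp = {name: 100.0 * p / total for name, p in powers.items()}
    tg = (
        powers["theta"] / powers["gamma"]
        if "theta" in powers and "gamma" in powers and powers["gamma"] > 0
        else np.nan
    )
    return BandPowerSummary(
        total_power=total,
        total_power_db=10.0 * np.log10(total / p_ref),
        rp=rp,
        tg_ratio=tg,
        p_ref=p_ref,
    )


def phase_power_change(
    rec,
    scheme: BandScheme | None = None,
    seg_len: float = 2.0,
    overlap: float = 0.5,
    channel: int = 0,
) -> PowerChange:
    """Stimulation-normalized total (and per-band) power change for a session.

    The recording's ``meta["phases"]`` must map ``pre`` / ``stim`` / ``post``
    to [start, stop] times in seconds. Power per phase is the integrated Welch
    PSD of the phase's concatenated data over the scheme's total range.
    """
    scheme = BandScheme() if scheme is None else scheme
    phases = rec.meta.get("phases")
    if not phases or not {"pre", "stim", "post"} <= set(phases):
        raise ValueError("recording meta lacks pre/stim/post phase labels")
    totals: dict[str, float] = {}
    bands: dict[str, dict[str, float]] = {}
    for name in ("pre", "stim", "post"):
        start, stop = phases[name]
        seg = rec.samples[channel, int(round(start * rec.fs)) : int(round(stop * rec.fs))]
        freqs, psd = welch_psd(seg, rec.fs, seg_len, overlap)
        summary = band_powers(freqs, psd, scheme)
        totals[name] = summary.total_power
        bands[name] = {
            b: summary.total_power * summary.rp[b] / 100.0 for b in scheme.bands
        }
    per_band = {
        b: PowerChange(
            pre=bands["pre"][b],
            stim=bands["stim"][b],
            post=bands["post"][b],
            change_pct=100.0 * (bands["stim"][b] - bands["pre"][b]) / bands["pre"][b],
            post_recovery_pct=100.0 * (bands["post"][b] - bands["pre"][b]) / bands["pre"][b],
        )
        for b in scheme.bands
    }
    return PowerChange(
        pre=totals["pre"],
        stim=totals["stim"],
        post=totals["post"],
        change_pct=100.0 * (totals["stim"] - totals["pre"]) / totals["pre"],
        post_recovery_pct=100.0 * (totals["post"] - totals["pre"]) / totals["pre"],
        per_band=per_band,
    )


def spectrogram(
    x: np.ndarray,
    fs: float,
    win: float = 1.0,
    step: float = 0.25,
    baseline: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Hanning-windowed power map, dB-scaled to a baseline.

    Returns ``(times, freqs, power_db)`` with ``power_db`` of shape
    (n_freqs, n_times). When ``baseline`` (start, stop in s) is given, each
    frequency bin is expressed in dB relative to its mean power over that
    window; otherwise relative to the mean over the whole signal.
    """
    nperseg = int(round(win * fs))
    if nperseg < 2:
        raise ValueError("window too short")
    noverlap = nperseg - int(round(step * fs))
    freqs, times, sxx = sps.spectrogram(
        np.asarray(x, dtype=float).ravel(),
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=max(0, noverlap),
        scaling="density",
        mode="psd",
    )
    if baseline is not None:
        sel = (times >= baseline[0]) & (times < baseline[1])
        if not sel.any():
            raise ValueError("baseline window contains no spectrogram frames")
    else:
        sel = np.ones_like(times, dtype=bool)
    ref = sxx[:, sel].mean(axis=1, keepdims=True)
    ref[ref == 0] = np.finfo(float).tiny
    power_db = 10.0 * np.log10(np.maximum(sxx, np.finfo(float).tiny) / ref)
    return times, freqs, power_db
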