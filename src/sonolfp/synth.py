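"""Synthetic LFP recording generator.

Emulates the statistical structure the analysis pipeline assumes:

* spontaneous background as a sum of independent band-limited Gaussian noise
  processes, one per canonical band (delta/theta/alpha/beta/gamma), each shaped
  by an ideal (FFT-domain) band filter and scaled to an exact share of the
  total variance, so that the relative band power of the generated signal is
  the specified composition by construction;
* stimulation-locked evoked deflections: a dominant-negative biphasic template
  (Gaussian trough with a smaller positive rebound) with per-trial amplitude
  and latency jitter;
* 50 Hz power-line interference plus odd harmonics with random phases;
* optional non-biological ultrasound artifact transients at stimulus onsets;
* three-phase (pre / stimulation / post) sessions in which the background
  power is raised by a multiplicative gain during the stimulation phase.

All randomness flows through a single seeded generator, so an identical spec
and seed reproduce the recording bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .protocol import StimProtocol
from .recording import Recording
from .spectral import CANONICAL_BANDS

__all__ = [
    "SynthSpec",
    "EvokedSpec",
    "ArtifactSpec",
    "make_background",
    "inject_evoked",
    "inject_line_noise",
    "build_session",
    "make_evoked_session",
    "evoked_template",
    "artifact_template",
]

_FRAC_TOL = 1e-9


@dataclass
class EvokedSpec:
    """Ultrasound-evoked deflection parameters.

    ``n1_amp`` is the trough magnitude in µV, ``n1_latency_ms`` the time from
    stimulus onset to the trough. ``width_ms`` is the Gaussian sigma of the
    negative lobe. Amplitude jitter is multiplicative (fraction of the mean,
    SD of a unit normal), latency jitter additive in ms. ``background_rms``
    is the residual background level (µV) used for dedicated evoked-potential
    sessions, where the deflection must be resolvable trial by trial.
    """

    n1_amp: float
    n1_latency_ms: float = 80.0
    width_ms: float = 15.0
    jitter_amp: float = 0.1
    jitter_lat_ms: float = 5.0
    background_rms: float = 5.0


@dataclass
class ArtifactSpec:
    """Non-biological ultrasound artifact: a damped high-frequency ring added
    at stimulus onsets with probability ``prob``."""

    amplitude: float = 100.0
    prob: float = 1.0
    ring_hz: float = 80.0
    decay_ms: float = 15.0


@dataclass
class SynthSpec:
    """Generative parameters for one simulated animal / group.

    ``band_fractions`` maps canonical band names to their share of total
    power (must sum to 1). ``total_rms`` sets the overall scale in µV.
    ``stim_power_gain`` is the fractional broadband power increase applied to
    the background during the stimulation phase (0.212 means +21.2%).
    """

    band_fractions: dict[str, float]
    total_rms: float = 50.0
    evoked: EvokedSpec | None = None
    stim_power_gain: float = 0.0
    line_noise_amp: float = 0.0
    line_harmonics: tuple[float, ...] = (150.0, 250.0, 350.0)
    artifact: ArtifactSpec | None = None
    fs: float = 1000.0
    phase_len: float = 150.0
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.band_fractions.values())
        if any(f < 0 for f in self.band_fractions.values()) or abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"band fractions must be non-negative and sum to 1, got {total}"
            )
        unknown = set(self.band_fractions) - set(CANONICAL_BANDS)
        if unknown:
            raise ValueError(f"unknown bands {sorted(unknown)}")
        if self.fs < 200.0:
            raise ValueError("fs must be at least 200 Hz (Nyquist for gamma)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_background(
    spec: SynthSpec, duration: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Spontaneous LFP background of the given duration (s), in µV.

    Sum of independent band-limited Gaussian processes; each band component
    carries exactly ``band_fractions[b] * total_rms**2`` of the variance.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = spec.rng() if rng is None else rng
    n = int(round(duration * spec.fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    out = np.zeros(n)
    for name, frac in spec.band_fractions.items():
        if frac == 0:
            continue
        lo, hi = CANONICAL_BANDS[name]
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            raise ValueError(f"no spectral support for band {name!r} at n={n}")
        # linear power roll-off inside each band edge keeps the composite
        # spectrum continuous (real LFP spectra have no steps) and the Welch
        # band-power estimator unbiased at the band boundaries
        f_band = freqs[mask]
        w = min(1.0, (hi - lo) / 4.0)
        ramp = np.clip(np.minimum((f_band - lo) / w, (hi - f_band) / w), 0.0, 1.0)
        spectrum = np.zeros(len(freqs), dtype=complex)
        spectrum[mask] = np.sqrt(ramp) * (
            rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
        )
        comp = np.fft.irfft(spectrum, n=n)
        sd = comp.std()
        target = np.sqrt(frac) * spec.total_rms
        out += comp * (target / sd)
    return out


def evoked_template(fs: float, width_ms: float = 15.0) -> tuple[np.ndarray, int]:
    """Unit-trough evoked template and the index of its trough.

    Dominant negative Gaussian lobe (sigma = ``width_ms``) followed by a
    smaller, broader positive rebound; trough value is exactly -1.
    """
    sigma = width_ms / 1000.0
    t = np.arange(-3.5 * sigma, 6.0 * sigma, 1.0 / fs)
    h = -np.exp(-(t**2) / (2 * sigma**2)) + 0.35 * np.exp(
        -((t - 2.5 * sigma) ** 2) / (2 * (1.5 * sigma) ** 2)
    )
    h /= np.abs(h.min())
    return h, int(np.argmin(h))


def inject_evoked(
    signal: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    evoked: EvokedSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Overlap-add jittered evoked deflections at the given onset times (s).

    Returns a new array; onsets whose template would fall outside the signal
    are skipped with a warning. ``n1_amp = 0`` leaves the signal unchanged.
    """
    rng = np.random.default_rng() if rng is None else rng
    out = np.asarray(signal, dtype=float).copy()
    if evoked is None or evoked.n1_amp == 0:
        return out
    h, trough = evoked_template(fs, evoked.width_ms)
    for t_on in np.atleast_1d(onsets):
        amp = evoked.n1_amp * max(0.0, 1.0 + evoked.jitter_amp * rng.standard_normal())
        lat = evoked.n1_latency_ms + evoked.jitter_lat_ms * rng.standard_normal()
        center = int(round((t_on + lat / 1000.0) * fs))
        start = center - trough
        stop = start + len(h)
        if start < 0 or stop > len(out):
            warnings.warn(f"evoked response at onset {t_on:.3f}s out of range; skipped")
            continue
        out[start:stop] += amp * h
    return out


def inject_line_noise(
    signal: np.ndarray,
    fs: float,
    amp50: float,
    harmonics: tuple[float, ...] = (150.0, 250.0, 350.0),
    harmonic_decay: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Add 50 Hz interference and odd harmonics with random phases.

    Harmonic k carries ``amp50 * harmonic_decay**k`` µV amplitude (so the
    default gives a 1 : 0.5 : 0.25 : 0.125 amplitude ladder).
    """
    rng = np.random.default_rng() if rng is None else rng
    out = np.asarray(signal, dtype=float).copy()
    if amp50 == 0:
        return out
    freqs = (50.0, *harmonics)
    if max(freqs) >= fs / 2:
        raise ValueError(f"harmonic {max(freqs)} Hz at or above Nyquist ({fs / 2} Hz)")
    t = np.arange(len(out)) / fs
    for k, f in enumerate(freqs):
        amp = amp50 * harmonic_decay**k
        out += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def artifact_template(fs: float, spec: ArtifactSpec) -> np.ndarray:
    """Unit-amplitude damped-ring artifact waveform (non-biological shape)."""
    dur = 6.0 * spec.decay_ms / 1000.0
    t = np.arange(0, dur, 1.0 / fs)
    w = np.sin(2 * np.pi * spec.ring_hz * t) * np.exp(-t / (spec.decay_ms / 1000.0))
    peak = np.abs(w).max()
    return w / peak if peak else w


def _inject_artifacts(
    signal: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    art: ArtifactSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    out = signal.copy()
    w = art.amplitude * artifact_template(fs, art)
    for t_on in np.atleast_1d(onsets):
        if rng.uniform() > art.prob:
            continue
        start = int(round(t_on * fs))
        stop = min(start + len(w), len(out))
        if start >= len(out):
            continue
        out[start:stop] += w[: stop - start]
    return out


def build_session(
    spec: SynthSpec,
    protocol: StimProtocol,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Three-phase (pre / stim / post) session as a single-channel Recording.

    Each phase lasts ``spec.phase_len`` s. During the stimulation phase the
    background is scaled so its power rises by ``stim_power_gain``; stimuli
    occur every SD + ISI, and evoked deflections / artifacts / line noise are
    injected per spec. Phase boundaries are stored in ``meta["phases"]``.
    """
    rng = spec.rng() if rng is None else rng
    plen = spec.phase_len
    pre = make_background(spec, plen, rng)
    stim = make_background(spec, plen, rng) * np.sqrt(1.0 + spec.stim_power_gain)
    post = make_background(spec, plen, rng)
    x = np.concatenate([pre, stim, post])
    onsets = np.asarray(protocol.onsets_in_phase(phase_start=plen))
    if spec.evoked is not None:
        x = inject_evoked(x, spec.fs, onsets, spec.evoked, rng)
    if spec.artifact is not None:
        x = _inject_artifacts(x, spec.fs, onsets, spec.artifact, rng)
    if spec.line_noise_amp:
        x = inject_line_noise(x, spec.fs, spec.line_noise_amp, spec.line_harmonics, rng=rng)
    meta = {
        "phases": {"pre": [0.0, plen], "stim": [plen, 2 * plen], "post": [2 * plen, 3 * plen]},
    }
    return Recording(samples=x[None, :], fs=spec.fs, stim_onsets=onsets, meta=meta)


def make_evoked_session(
    spec: SynthSpec,
    n_trials: int = 50,
    protocol: StimProtocol | None = None,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Stimulation-only session for per-trial evoked-potential quantification.

    The background uses the group's band composition at the evoked spec's
    residual ``background_rms`` level; ``n_trials`` stimuli are delivered at
    the protocol cadence with 2 s padding at either end.
    """
    if spec.evoked is None:
        raise ValueError("spec has no evoked parameters")
    protocol = StimProtocol() if protocol is None else protocol
    rng = spec.rng() if rng is None else rng
    duration = 4.0 + n_trials * protocol.cycle
    quiet = SynthSpec(
        band_fractions=dict(spec.band_fractions),
        total_rms=spec.evoked.background_rms,
        fs=spec.fs,
        phase_len=spec.phase_len,
    )
    x = make_background(quiet, duration, rng)
    onsets = 2.0 + np.arange(n_trials) * protocol.cycle
    x = inject_evoked(x, spec.fs, onsets, spec.evoked, rng)
    if spec.artifact is not None:
        x = _inject_artifacts(x, spec.fs, onsets, spec.artifact, rng)
    if spec.line_noise_amp:
        x = inject_line_noise(x, spec.fs, spec.line_noise_amp, spec.line_harmonics, rng=rng)
    return Recording(samples=x[None, :], fs=spec.fs, stim_onsets=onsets, meta={})
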