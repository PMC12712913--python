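"""Cleaning chain: filters, epoching, baseline, artifact rejection."""

import numpy as np
import pytest

from sonolfp import (
    EvokedSpec,
    FilterSpec,
    Recording,
    apply_filters,
    baseline_correct,
    epoch,
    inject_evoked,
    reject_artifacts,
)
from sonolfp.preprocess import Epoch, EmptyEpochError
from sonolfp.synth import ArtifactSpec, artifact_template

FS = 1000.0


def _rec(x, onsets=()):
    return Recording(samples=np.atleast_2d(x), fs=FS, stim_onsets=list(onsets))


def _sine(freq, dur=20.0):
    t = np.arange(int(dur * FS)) / FS
    return np.sin(2 * np.pi * freq * t)


class TestFilters:
    def test_notch_kills_50hz(self):
        out = apply_filters(_rec(_sine(50.0))).samples[0]
        mid = slice(int(2 * FS), int(18 * FS))  # avoid filter edges
        in_rms = np.sqrt((_sine(50.0)[mid] ** 2).mean())
        out_rms = np.sqrt((out[mid] ** 2).mean())
        assert 20 * np.log10(in_rms / out_rms) > 40.0

    def test_passband_preserves_10hz(self):
        out = apply_filters(_rec(_sine(10.0))).samples[0]
        mid = slice(int(2 * FS), int(18 * FS))
        assert np.sqrt((out[mid] ** 2).mean()) == pytest.approx(
            np.sqrt(0.5), rel=0.05
        )

    def test_band_edges_attenuation(self):
        """Zero-phase order-2 Butterworth: -6 dB power at the band edges."""
        from scipy import signal as sps

        sos = sps.butter(2, (0.5, 100.0), btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[0.5, 10.0, 100.0], fs=FS)
        gain2 = np.abs(h) ** 2  # squared once more by forward-backward pass
        assert (gain2[0] ** 2) == pytest.approx(0.25, rel=0.05)
        assert (gain2[2] ** 2) == pytest.approx(0.25, rel=0.05)
        assert (gain2[1] ** 2) == pytest.approx(1.0, abs=0.02)

    def test_linearity(self, rng):
        x, y = rng.normal(size=(2, 5000))
        fa = apply_filters(_rec(2.0 * x + 3.0 * y)).samples[0]
        fb = 2.0 * apply_filters(_rec(x)).samples[0] + 3.0 * apply_filters(_rec(y)).samples[0]
        assert np.allclose(fa, fb, atol=1e-9)

    def test_zero_phase_preserves_latency(self):
        """Filtering must not shift the injected trough by more than 1 sample."""
        ev = EvokedSpec(n1_amp=40.0, n1_latency_ms=80.0, jitter_amp=0, jitter_lat_ms=0)
        x = inject_evoked(np.zeros(4000), FS, [2.0], ev, np.random.default_rng(0))
        before = np.argmin(x)
        after = np.argmin(apply_filters(_rec(x)).samples[0])
        assert abs(int(after) - int(before)) <= 1

    def test_fs_too_low_rejected(self):
        rec = Recording(samples=np.zeros((1, 1000)), fs=150.0)
        with pytest.raises(ValueError, match="band"):
            apply_filters(rec, FilterSpec(band=(0.5, 100.0)))


class TestEpoching:
    def test_all_onsets_inside(self):
        onsets = 2.0 + np.arange(10) * 3.3
        rec = _rec(np.zeros(int(40 * FS)), onsets)
        ep = epoch(rec)
        assert ep.n_trials == 10
        assert ep.data.shape[1] == int(3.0 * FS)

    def test_edge_onset_dropped(self):
        rec = _rec(np.zeros(int(10 * FS)), [0.5, 5.0])
        with pytest.warns(UserWarning, match="dropped"):
            ep = epoch(rec, window=(-1.0, 2.0))
        assert ep.n_trials == 1

    def test_no_usable_onsets(self):
        rec = _rec(np.zeros(int(2 * FS)), [0.1])
        with pytest.warns(UserWarning):
            with pytest.raises(EmptyEpochError):
                epoch(rec)

    def test_trials_match_session_onsets(self, fast_protocol):
        from sonolfp import build_session
        from sonolfp.synth import SynthSpec

        spec = SynthSpec(
            band_fractions={"delta": 0.5, "theta": 0.5}, phase_len=30.0, seed=1
        )
        rec = build_session(spec, fast_protocol)
        assert epoch(rec).n_trials == len(rec.stim_onsets)


class TestBaseline:
    def test_constant_offset_removed(self):
        ep = Epoch(data=np.full((1, 3000), 7.0), fs=FS)
        out = baseline_correct(ep)
        assert np.allclose(out.data, 0.0)

    def test_idempotent_on_zero_mean(self, rng):
        data = rng.normal(size=(4, 3000))
        ep = baseline_correct(Epoch(data=data, fs=FS))
        again = baseline_correct(ep)
        assert np.allclose(ep.data, again.data)

    def test_trough_amplitude_unchanged_with_flat_baseline(self):
        ev = EvokedSpec(n1_amp=25.0, jitter_amp=0, jitter_lat_ms=0)
        x = inject_evoked(np.zeros(4000), FS, [2.0], ev, np.random.default_rng(0))
        ep = epoch(_rec(x, [2.0]))
        out = baseline_correct(ep)
        assert out.data.min() == pytest.approx(-25.0, abs=1e-9)


class TestArtifactRejection:
    @pytest.fixture
    def template(self):
        return artifact_template(FS, ArtifactSpec())

    def _trials(self, template, rng, n=20, snr=0.0):
        data = rng.normal(size=(n, 3000))
        if snr > 0:
            scale = snr * data.std()
            data[:, 1000 : 1000 + len(template)] += scale * template
        return Epoch(data=data, fs=FS)

    def test_scaled_template_flagged(self, template, rng):
        ep = self._trials(template, rng, n=5, snr=50.0)
        out = reject_artifacts(ep, template, rho_min=0.8)
        assert not out.kept_mask.any()

    def test_noise_trials_kept(self, template, rng):
        ep = self._trials(template, rng, n=20, snr=0.0)
        out = reject_artifacts(ep, template, rho_min=0.8)
        assert out.kept_mask.mean() >= 0.95

    def test_rho_above_one_never_flags(self, template, rng):
        ep = self._trials(template, rng, n=5, snr=50.0)
        out = reject_artifacts(ep, template, rho_min=1.0 + 1e-6)
        assert out.kept_mask.all()

    def test_identical_template_always_flagged_at_rho_one(self, template):
        data = np.zeros((1, 3000))
        data[0, 1100 : 1100 + len(template)] = 5.0 * template
        out = reject_artifacts(Epoch(data=data, fs=FS), template, rho_min=1.0)
        assert not out.kept_mask[0]

    def test_flag_rate_monotone_in_snr(self, template):
        rng = np.random.default_rng(77)
        rates = []
        for snr in (0.0, 1.0, 3.0, 10.0):
            ep = self._trials(template, rng, n=30, snr=snr)
            out = reject_artifacts(ep, template, rho_min=0.6)
            rates.append(1.0 - out.kept_mask.mean())
        assert all(b >= a - 1e-9 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]

    def test_zero_variance_template_rejected(self, rng):
        ep = Epoch(data=rng.normal(size=(2, 3000)), fs=FS)
        with pytest.raises(ValueError, match="zero-variance"):
            reject_artifacts(ep, np.ones(50), rho_min=0.8)
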