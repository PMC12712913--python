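"""Synthetic-recording generator: determinism, composition, injections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonolfp import (
    EvokedSpec,
    SynthSpec,
    apply_filters,
    band_powers,
    build_session,
    inject_evoked,
    inject_line_noise,
    load_preset,
    make_background,
    welch_psd,
)
from sonolfp.presets import available_presets
from sonolfp.synth import evoked_template


def _spec(fractions, **kw):
    names = ("delta", "theta", "alpha", "beta", "gamma")
    return SynthSpec(band_fractions=dict(zip(names, fractions)), **kw)


def _recovered_rp(spec, duration=150.0, filtered=False):
    x = make_background(spec, duration)
    if filtered:
        from sonolfp import Recording

        x = apply_filters(Recording(samples=x[None, :], fs=spec.fs)).samples[0]
    freqs, psd = welch_psd(x, spec.fs)
    return band_powers(freqs, psd).rp


class TestBackground:
    def test_seeded_determinism(self):
        spec = _spec((0.4, 0.3, 0.1, 0.1, 0.1), seed=7)
        assert np.array_equal(make_background(spec, 10.0), make_background(spec, 10.0))

    def test_degenerate_delta_band(self):
        rp = _recovered_rp(_spec((1.0, 0, 0, 0, 0), seed=0), duration=60.0)
        assert rp["delta"] >= 95.0

    def test_total_rms_exact(self):
        spec = _spec((0.4, 0.3, 0.1, 0.1, 0.1), total_rms=42.0, seed=3)
        x = make_background(spec, 30.0)
        # per-band variances are normalized exactly; cross-band sample
        # covariance adds a small random term
        assert np.sqrt((x**2).mean()) == pytest.approx(42.0, rel=0.05)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _spec((0.5, 0.5, 0.5, 0, 0))

    @settings(max_examples=5, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.05, 1.0), min_size=5, max_size=5), st.integers(0, 100))
    def test_estimator_recovers_simplex_fractions(self, raw, seed):
        """Generator -> Welch RP round-trip within 3 points per band.

        Checked against the spectral estimator itself; the order-2 bandpass of
        the cleaning chain additionally shaves band edges (chiefly gamma near
        100 Hz), a known bias covered by the preset-level end-to-end tests.
        """
        fracs = np.asarray(raw) / np.sum(raw)
        spec = _spec(fracs, seed=seed)
        rp = _recovered_rp(spec, duration=150.0, filtered=False)
        for frac, band in zip(fracs, ("delta", "theta", "alpha", "beta", "gamma")):
            assert abs(rp[band] - 100.0 * frac) <= 3.0


class TestEvoked:
    def test_trough_exact_on_zero_background(self):
        fs = 1000.0
        ev = EvokedSpec(n1_amp=40.0, n1_latency_ms=80.0, jitter_amp=0, jitter_lat_ms=0)
        x = inject_evoked(np.zeros(2000), fs, [0.5], ev, np.random.default_rng(0))
        trough = np.argmin(x)
        assert x[trough] == pytest.approx(-40.0)
        assert trough / fs == pytest.approx(0.5 + 0.080, abs=1.5 / fs)

    def test_zero_amplitude_is_identity(self):
        x = np.random.default_rng(1).normal(size=1000)
        ev = EvokedSpec(n1_amp=0.0)
        assert np.array_equal(inject_evoked(x, 1000.0, [0.3], ev), x)

    def test_out_of_range_onset_warns_and_skips(self):
        ev = EvokedSpec(n1_amp=10.0, jitter_amp=0, jitter_lat_ms=0)
        with pytest.warns(UserWarning, match="out of range"):
            out = inject_evoked(np.zeros(100), 1000.0, [0.09], ev, np.random.default_rng(0))
        assert np.all(out == 0)

    def test_template_dominant_negative(self):
        h, trough = evoked_template(1000.0, 15.0)
        assert h[trough] == pytest.approx(-1.0)
        assert h.max() < 0.5  # rebound clearly smaller than the trough

    def test_mean_trial_amplitude_matches_preset(self):
        """Jittered injection preserves the preset mean amplitude (40.16 µV)."""
        fs = 1000.0
        ev = EvokedSpec(n1_amp=40.16, n1_latency_ms=80.0)
        rng = np.random.default_rng(2024)
        onsets = 1.0 + np.arange(200) * 1.0
        x = inject_evoked(np.zeros(int(202 * fs)), fs, onsets, ev, rng)
        troughs = [
            -x[int((t + 0.03) * fs) : int((t + 0.2) * fs)].min() for t in onsets
        ]
        assert np.mean(troughs) == pytest.approx(40.16, abs=1.0)


class TestLineNoise:
    def test_peak_present_then_notched(self):
        fs = 1000.0
        rng = np.random.default_rng(5)
        x = rng.normal(size=int(30 * fs))
        noisy = inject_line_noise(x, fs, amp50=10.0, rng=rng)
        freqs, psd = welch_psd(noisy, fs)
        i50 = np.argmin(np.abs(freqs - 50.0))
        passband = (freqs > 5) & (freqs < 45)
        assert psd[i50] > 10 * np.median(psd[passband])
        from sonolfp import FilterSpec, Recording

        clean = apply_filters(Recording(samples=noisy[None, :], fs=fs), FilterSpec())
        _, psd_clean = welch_psd(clean.samples[0], fs)
        assert psd_clean[i50] < 2 * np.median(psd_clean[passband])

    def test_zero_amplitude_identity(self):
        x = np.arange(100.0)
        assert np.array_equal(inject_line_noise(x, 1000.0, 0.0), x)

    def test_harmonic_amplitude_ladder(self):
        fs = 1000.0
        x = inject_line_noise(
            np.zeros(int(60 * fs)), fs, amp50=8.0, rng=np.random.default_rng(0)
        )
        freqs, psd = welch_psd(x, fs, seg_len=4.0)
        peaks = [psd[np.argmin(np.abs(freqs - f))] for f in (50, 150, 250, 350)]
        ratios = np.array(peaks) / peaks[0]
        # amplitude halves per harmonic -> power quarters
        assert np.allclose(ratios, [1, 0.25, 0.0625, 0.015625], rtol=0.1)

    def test_harmonic_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            inject_line_noise(np.zeros(100), 500.0, 1.0, harmonics=(350.0,))


class TestSession:
    def test_layout_and_onsets(self, fast_protocol):
        spec = _spec((0.4, 0.3, 0.1, 0.1, 0.1), phase_len=30.0, seed=9)
        rec = build_session(spec, fast_protocol)
        assert rec.duration == pytest.approx(90.0)
        expected = int(np.floor(fast_protocol.phase_len / fast_protocol.cycle))
        assert len(rec.stim_onsets) == expected == 9
        assert rec.stim_onsets[0] == pytest.approx(30.0)
        assert rec.meta["phases"]["stim"] == [30.0, 60.0]

    def test_full_protocol_gives_45_onsets(self, protocol):
        spec = _spec((1.0, 0, 0, 0, 0), seed=0)
        rec = build_session(spec, protocol)
        assert len(rec.stim_onsets) == 45
        assert rec.duration == pytest.approx(450.0)

    def test_zero_gain_power_balance(self, fast_protocol):
        from sonolfp import phase_power_change

        spec = _spec((0.4, 0.3, 0.1, 0.1, 0.1), phase_len=30.0, stim_power_gain=0.0, seed=4)
        rec = build_session(spec, fast_protocol)
        pc = phase_power_change(rec)
        assert abs(pc.change_pct) < 8.0  # estimator noise only

    def test_determinism(self, fast_protocol):
        spec = _spec((0.4, 0.3, 0.1, 0.1, 0.1), phase_len=30.0, seed=11)
        a = build_session(spec, fast_protocol)
        b = build_session(spec, fast_protocol)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.stim_onsets, b.stim_onsets)


class TestPresets:
    def test_all_groups_available(self):
        assert set(available_presets()) == {"CON", "MscL-G22S", "MscL-G22N", "MscS"}

    def test_g22n_composition(self):
        spec = load_preset("MscL-G22N")
        assert spec.band_fractions["delta"] == pytest.approx(0.6029)
        assert sum(spec.band_fractions.values()) == pytest.approx(1.0)

    def test_intensity_attaches_gain_and_evoked(self):
        spec = load_preset("MscL-G22S", intensity=400)
        assert spec.stim_power_gain == pytest.approx(0.212)
        assert spec.evoked.n1_amp == pytest.approx(40.16)
        none = load_preset("MscS", intensity=400)
        assert none.evoked is None

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            load_preset("nope")
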