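# Group presets for the synthetic-recording generator.
#
# Printed study values (band composition for MscL-G22N; stimulation power
# gains; 400 mW/cm² evoked amplitudes; group total power in dB re 1 µV²)
# parameterize the generator directly. Entries marked "synthetic" are not
# printed anywhere and are representative values chosen for realism: band
# compositions for CON / MscL-G22S / MscS, evoked amplitudes below
# 400 mW/cm², all evoked latencies, and line-noise levels.
#
# total_rms_uv is derived from the group's total power in dB by adopting a
# 1 µV² reference: rms = sqrt(10^(dB/10)).
#
# stim_power_gain maps intensity (mW/cm²) -> fractional broadband power gain
# during the stimulation phase (0.212 = +21.2%).

CON:
  band_fractions: {delta: 0.45, theta: 0.28, alpha: 0.10, beta: 0.12, gamma: 0.05}  # synthetic
  total_rms_uv: 68.08            # 36.66 dB re 1 µV²
  line_noise_uv: 5.0             # synthetic
  stim_power_gain: {100: 0.1492, 250: 0.15, 400: 0.15}   # 250/400 synthetic (no change across intensities)
  evoked:
    background_rms_uv: 5.0
    by_intensity:
      100: null                  # no detectable response
      250: {n1_amp_uv: 12.0, n1_latency_ms: 110.0, width_ms: 15.0, jitter_amp: 0.1, jitter_lat_ms: 5.0}  # synthetic (modest)
      400: {n1_amp_uv: 36.2, n1_latency_ms: 90.0, width_ms: 15.0, jitter_amp: 0.1, jitter_lat_ms: 5.0}

MscL-G22S:
  band_fractions: {delta: 0.47, theta: 0.27, alpha: 0.10, beta: 0.11, gamma: 0.05}  # synthetic
  total_rms_uv: 38.55            # 31.72 dB re 1 µV²
  line_noise_uv: 5.0             # synthetic
  stim_power_gain: {100: 0.0971, 250: 0.0667, 400: 0.212}
  evoked:
    background_rms_uv: 5.0
    by_intensity:
      100: {n1_amp_uv: 15.0, n1_latency_ms: 120.0, width_ms: 15.0, jitter_amp: 0.1, jitter_lat_ms: 5.0}  # synthetic
      250: {n1_amp_uv: 25.0, n1_latency_ms: 100.0, width_ms: 15.0, jitter_amp: 0.1, jitter_lat_ms: 5.0}  # synthetic
      400: {n1_amp_uv: 40.16, n1_latency_ms: 80.0, width_ms: 15.0, jitter_amp: 0.1, jitter_lat_ms: 5.0}

MscL-G22N:
  band_fractions: {delta: 0.6029, theta: 0.2057, alpha: 0.0851, beta: 0.0957, gamma: 0.0106}
  total_rms_uv: 49.66            # 33.92 dB re 1 µV²
  line_noise_uv: 5.0             # synthetic
  stim_power_gain: {100: 0.0342, 250: 0.03, 400: 0.03}   # 250/400 synthetic (minimal response)
  evoked:
    background_rms_uv: 5.0
    by_intensity:
      100: null
      250: null
      400: {n1_amp_uv: 24.2, n1_latency_ms: 95.0, width_ms: 15.0, jitter_amp: 0.1, jitter_lat_ms: 5.0}

MscS:
  band_fractions: {delta: 0.40, theta: 0.30, alpha: 0.10, beta: 0.13, gamma: 0.07}  # synthetic
  total_rms_uv: 118.41           # 41.47 dB re 1 µV²
  line_noise_uv: 5.0             # synthetic
  stim_power_gain: {100: 0.1995, 250: 0.084, 400: 0.0002}
  evoked:
    background_rms_uv: 5.0
    by_intensity:
      100: null
      250: null
      400: null                  # no significant evoked response
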