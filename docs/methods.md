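# Methods

This note documents the models, estimators, and design choices behind
`sonolfp`, and what the synthetic-data validation does and does not
demonstrate.

## Signal model and generator

The generator treats a spontaneous LFP as a sum of five independent
band-limited Gaussian processes, one per canonical band (δ 0.5–4, θ 4–8,
α 8–12, β 12–30, γ 30–100 Hz). Each component is synthesized in the frequency
domain (complex Gaussian spectrum restricted to its band) and scaled so that
its sample variance is exactly `f_b · RMS²`, where the band fractions `f_b`
sum to one. The relative band power of a generated signal therefore equals
the specified composition by construction, which is what makes the
generator → pipeline recovery tests meaningful.

Two refinements matter numerically:

- **Band-edge tapers.** Each component's power density rolls off linearly
  over ≤1 Hz inside its own band edges. A piecewise-flat spectrum with steps
  at the band boundaries would bias Welch band power: the Hanning window
  smears power symmetrically across a boundary, and when the densities on the
  two sides differ (δ density is ~3× θ density in the G22N composition) the
  net transfer is one-sided, costing ~2–3 RP points at the 4 Hz edge alone.
  With continuous (tapered) spectra the smearing is balanced and the
  estimator is unbiased to well under one point. Real LFP spectra are
  continuous, so the taper also improves realism.
- **Exact variance normalization** per component, so Parseval-type checks
  hold tightly.

Evoked responses are a dominant-negative biphasic template — a Gaussian
trough (σ = `width_ms`, default 15 ms) followed by a smaller, broader
positive rebound — normalized to unit trough, placed `n1_latency_ms` after
each onset, with multiplicative amplitude jitter (SD = 10% of the mean) and
additive latency jitter (SD = 5 ms). Line interference is added as sinusoids
at 50 Hz and odd harmonics with amplitudes halving per harmonic and random
phases. Optional non-biological artifacts are damped 80 Hz rings at onsets.

A session is three concatenated 150 s phases (pre / stimulation / post). The
stimulation-phase background is scaled by `√(1 + g)` so its power rises by
the fractional gain `g`; stimuli are delivered every SD + ISI = 3.3 s,
giving `floor(150/3.3) = 45` onsets per phase. All randomness flows through
one seeded generator: identical spec + seed reproduce the recording exactly.

### Presets

Group presets encode the study conditions the package is validated against:
the MscL-G22N band composition (60.29/20.57/8.51/9.57/1.06 %), per-intensity
stimulation power gains (e.g. MscL-G22S: +9.71/+6.67/+21.2 % at 100/250/400
mW/cm²), and 400 mW/cm² evoked amplitudes (36.2/40.16/24.2 µV for
CON/G22S/G22N; none for MscS). Values not reported anywhere — band
compositions for the other groups, sub-maximal evoked amplitudes, all
latencies, line-noise levels — are fixed representative choices, marked
`synthetic` in `presets/presets.yaml`, and are not used as numeric targets.
Group RMS scales derive from the groups' total power in dB by adopting a
1 µV² dB reference (the reference is otherwise unconstrained); this yields
38–118 µV RMS, a realistic hippocampal LFP range.

Dedicated evoked-potential sessions use a reduced residual background
(5 µV RMS, same band composition). Per-trial N1 quantification presupposes
that single-trial deflections are resolvable — the study reports trial-level
n per condition — so the evoked preset places the trough SNR in that regime
(≈8 at the 40 µV amplitude); at the full spontaneous background (≈40–70 µV
RMS) single-trial detection is impossible for a 40 µV trough and only
trial-averaged detection would apply.

## Cleaning chain

Notches (IIR, Q = 30) at 50/150/250/350 Hz, then an order-2 Butterworth
0.5–100 Hz bandpass. Filtering is zero-phase (forward–backward) by default
because N1 latency is a reported outcome and causal filtering would delay
it; the effective order doubles, so the band edges sit at −6 dB rather than
−3 dB. Causal application is available via `FilterSpec(zero_phase=False)`.
A consequence worth knowing: the gentle order-2 skirts attenuate the upper
γ range noticeably (≈25% of a flat 30–100 Hz band), so pipeline-recovered
RP is biased by up to ~1 point for δ-dominated compositions and more for
γ-heavy ones. The estimator-level recovery property is therefore tested
against the Welch stage directly, and end-to-end recovery is validated at
the study compositions, where γ is small.

Epochs span −1 to +2 s around each onset; trials whose window would cross a
recording edge are dropped (not padded). Baseline correction subtracts the
per-trial mean over −1–0 s. Artifact rejection computes the maximal
normalized (Pearson) cross-correlation between a template and the 0–0.5 s
segment of each trial and discards trials at or above `rho_min` (default
0.8). The template-matching criterion in the source experiments is
qualitative; the correlation threshold is the package's operationalization.

## Spectral estimators

Welch PSD with 2 s Hanning segments, 50% overlap, density scaling: 0.5 Hz
resolution, matching the lower δ edge. Band power is the trapezoidal
integral of the PSD over the closed band interval with the PSD linearly
interpolated at both edges; adjacent bands share the edge ordinate, so the
five band powers partition the 0.5–100 Hz total exactly and RP sums to 100%
identically. Total power in dB uses a configurable reference, default 1 µV².
The θ/γ ratio is computed per recording (ratio of that recording's band
powers) and should be averaged across subjects as a mean of ratios; it is
reported as a dimensionless power ratio. Phase power change applies the
Welch estimator to each phase's concatenated data and reports
`(P_stim − P_pre)/P_pre × 100` plus the analogous post-phase recovery
statistic, totals and per band.

Spectrograms are short-time Hanning power maps expressed in dB per frequency
bin relative to the bin's mean power over a baseline window. Single-frame
log-power carries the χ² log bias (≈−2.5 dB for one segment), so averaged
comparisons should be made in the linear domain, as the tests do.

## N1 detection

Traces are optionally smoothed with a 5 ms moving average (disableable).
The significance floor defaults to 3× the pre-onset SD of the (smoothed)
trace; an explicit floor can be supplied. The "first negative deflection"
is operationalized as the **first contiguous excursion below the floor**
within 0–500 ms; amplitude and latency are read at the excursion's minimum.
Reading the excursion extremum rather than the literal first local minimum
matters at realistic SNR: noise ripples on the trough's descending limb
create shallow early minima that would otherwise truncate the measurement
and bias amplitude low by ~1–2 µV at SNR 8. Distinct troughs separated by a
return above the floor remain separate deflections, and the earlier one
wins regardless of depth. Trials with no qualifying excursion are
non-responses: excluded from amplitude/latency means, reported as a rate.

## Dosimetry and bio-heat

Duty cycle, Ispta↔Isppa, and MI are closed forms. The pressure–intensity
pairs (100/250/400 mW/cm² ↔ 0.15/0.25/0.35 MPa) are empirical hydrophone
calibrations and are looked up, never derived — they are inconsistent with
the plane-wave relation `I = p²/2ρc` (which over-predicts ~4×), so the
plane-wave converter is shipped separately and labeled approximate.

The thermal estimate is a zero-dimensional Pennes-style balance at the
focus: heating `dT/dt = 2αI/(ρc)` while the transducer is on (I is the
temporal-average intensity during sonication, i.e. the Ispta level), and
Newtonian perfusion cooling `−T/τ_perf` throughout. Defaults are standard
brain-tissue values: α = 0.04 Np/cm at 1 MHz, ρ = 1040 kg/m³,
c = 3630 J/(kg·K), τ_perf = 60 s; all configurable, and τ_perf = ∞ disables
cooling. The piecewise-constant ODE is solved exactly per on/off segment
(the trace step controls resolution only), so the integrator matches the
no-cooling closed form `ΔT = 2αIt/ρc` to machine precision. For the 50-pulse
train at 400 mW/cm² the model gives a peak rise of ≈0.044 °C, comfortably
under the 0.2 °C bound; this is an order-of-magnitude safety estimate, not a
replacement for field-resolved thermal simulation.

## Statistics

`compare_groups` gates on Shapiro–Wilk per group at α = 0.05: any failure
switches the whole measure to Kruskal–Wallis with two-sided Dunn z-tests
against the control group, otherwise one-way ANOVA with Dunnett's test
(scipy). Dunn's test uses pooled mid-ranks with tie correction and
Bonferroni adjustment over the vs-control comparisons; the adjustment choice
is the package's, as is treating a constant sample as passing the normality
gate. Levene's test is computed and reported but advisory only. The suite
verifies Dunn p-values against a label-permutation null of the pooled
rank-mean difference and checks the empirical type-I error of the whole
battery (~5% over 1000 null simulations).

## Problem sizes and limitations

Validation runs at fs = 1 kHz (the LFP band ends at 100 Hz; 20 kHz
acquisition-rate synthesis is available but unnecessary for spectral
content), 150 s phases, five seeds for stochastic recoveries, and 50-trial
evoked sessions. Stochastic recovery accuracy at these sizes is ~±1 RP
point, ~±1 point of power change, and ~±1 µV of mean N1 amplitude.

What passing tests show: the estimators are unbiased and correctly scaled on
signals with the assumed statistical structure, and the pipeline recovers
the generator's parameters at the study's printed operating points. What
they do not show: performance on real recordings with non-stationary
backgrounds, 1/f spectra, movement or chewing artifacts beyond the modeled
template, electrode drift, or volume-conduction structure — none of which
the generator emulates. Absolute-dB totals, behavioral group means, and any
statistic that depends on real animals are out of reach of the synthetic
validation and are not asserted anywhere.
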