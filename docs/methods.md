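# Methods

This note documents the models, parameter choices and numerical decisions
behind `strokephys`, and what the synthetic-data generators do and do not
emulate.

## Evoked field-potential scoring

Recordings are multichannel voltage series (millivolts) from a laminar probe
with uniformly spaced contacts (default 16 channels, 100 µm spacing, channel
1 most superficial), with stimulus onset times attached. Epochs are cut
around each stimulus and averaged per channel; trials whose window exceeds
the record are dropped with a warning. SEM is the across-trial SD (ddof 1)
over √n; a single trial reports SEM 0.

Component scoring follows the baseline-to-peak rule: the baseline is the
mean over [−50, 0) ms; the early negative component is `baseline − min` over
the [5, 35] ms search window and the late positive one `max − baseline` over
[35, 80] ms, both clamped at zero, with latencies at the extremum samples.
The search windows were chosen to bracket the components' physiological
latency ranges (negative peak 17–26 ms, positive 40–60 ms) with margin, and
are configurable. Per-channel amplitudes are pooled into four contiguous
layer groups (Sup, Sup/Middle, Middle/Deep, Deep — four channels each by
default); the exact channel-to-layer boundaries are a convention, not an
anatomical claim.

The paired-pulse ratio at ISI ∈ {50, 100, 200} ms measures both responses
peak-trough (window max minus window min) over [5, ISI) ms after pulse 1 and
[5, min(ISI, 80)] ms after pulse 2. Peak-trough for A2 avoids the altered
baseline preceding the second pulse; using the same rule for A1 keeps the
ratio symmetric (a `baseline_to_peak` mode for A1 is available). Channel
reliability is judged on the baseline-to-trough deflection of the first
response against `k × pre-stimulus SD` (default k = 3): peak-trough of pure
noise would always clear a 3-SD floor (the expected range of ~45 noise
samples is ≈ 4.5 SD), so the deflection — which stays near 2 SD for noise —
is the discriminating statistic. Unreliable channels report NaN.

Input/output curves use the deep-pool negative amplitude per light
intensity; the saturation intensity is the smallest intensity reaching 95%
of the maximum observed amplitude ("reached saturation" needs an operational
threshold; 95% is configurable). Fibre irradiance scales linearly between
the measured maximum power and its calibrated irradiance
(10 mW ↔ 79.55 mW/mm² by default).

## Inverse current source density

The step method assumes the CSD constant within depth slabs
`[z_i − h/2, z_i + h/2]` over discs of radius R centred on the probe axis.
The potential at electrode j from a slab of unit CSD has the closed form
used in `step_forward_matrix` (antiderivative of
`√(R² + u²) − |u|`); the CSD is `F⁻¹V` per time sample (direct solve; the
16×16 system is far from singular for sensible geometry). Defaults
σ = 0.3 S/m and R = 500 µm are standard cortical values; they scale the map
but cannot move extrema across channels, which is what the analyses rely
on. The second-difference estimate `−σ Δ²V/h²` with Vaknin end-channel
duplication is provided as an independent cross-check; both outputs are
sign-inverted so sinks are positive (warm in the usual display).

## Multi-unit activity

The wide-band signal is band-passed 300–10,000 Hz with a 4th-order
Butterworth applied forward-backward (zero phase, so latencies are not
shifted), then RMS'd in a centred sliding window (default 1 ms) per trial,
then averaged across trials — rectifying before averaging preserves spiking
power that would cancel in the mean trace. "Sample-by-sample RMS" is
ambiguous between instantaneous |x| and windowed RMS; the windowed form was
chosen because it has a well-defined closed form on test signals (a sinusoid
of amplitude a gives a/√2). Optional normalization divides each channel by
its maximum in the first-response window so depth profiles are comparable.
Near epoch edges the centred window pads by edge replication; quantitative
assertions should use interior samples.

## Reaching kinematics

The tangential speed is computed from the tracked positions by central
differences and smoothed with a 5-sample moving average (≈ 42 ms at
120 frames/s); ArcLen is the summed segment length, AUC the absolute
shoelace area of the path closed by the endpoint-to-start chord, Mean Speed
the average of the speed profile over the whole reach-and-retract movement,
and Smoothness the count of speed peaks with prominence at least 10% of the
maximum speed. The smoothing window and prominence fraction are not
physiological constants; the defaults were chosen for noise robustness and
are exposed. A moving but monotone-speed trajectory counts as one peak.
Only correct (successful) trials are meant to enter the metrics.

The colour tracker thresholds green dominance `G − max(R, B)` (8-bit
channels, default threshold 40), keeps the largest connected component and
takes its dominance-weighted centroid — weighting by the colour contrast
recovers sub-pixel positions from the anti-aliased dye edge (≤ 0.05 px on
rendered test discs). Empty frames are linearly interpolated and flagged;
a trial with more than 25% empty frames is rejected.

## Platform metrics and behavioral scores

Attempts are local maxima of the (50 ms moving-average smoothed) force trace
above a 0.05 N noise floor during which the handle stayed within 0.5 mm over
±100 ms; the smoothing prevents sensor noise from splitting one pulse into
several maxima, and the stationarity test excludes the successful pull.
The t-target is the time until the position first returns within 0.5 mm of
zero; with a smooth retraction profile this precedes the exact completion
time by up to ~0.1 s, which is the resolution the position tolerance
implies. The noise floor, position tolerance and coincidence window are
configurable; none are stated constants of the task.

Behavioral scores are direct formulas: foot-fault percentage
`100 × faults/(faults + correct)` per limb; asymmetry index
`(unimpaired − impaired)/(unimpaired + impaired)` wall contacts, so +1 means
exclusive use of the unimpaired limb (the cited index's sign convention is
not reproduced in the source; this orientation is documented here); reach
error percentage over total attempts; lesion volume
`Σ areas × 0.05 mm × 6`. Power for the two-sample t-test uses the
noncentral t distribution with df = 2n − 2 and noncentrality `d√(n/2)`;
the one-tailed default reproduces the design value (d = 1.75, n = 5 →
power 0.810; two-tailed would give 0.680).

## Synthetic-data generators

The generators are phenomenological: they reproduce signal shapes and
effect directions, not biophysics.

**Evoked LFP.** Each stimulus evokes, on every channel, a negative and a
positive raised-cosine (Hann) lobe. Compact support is deliberate: negative
lobes (half-width 6 ms, latency drawn on the sample grid within 18–25 ms)
and positive lobes (half-width 10 ms, latency 42–48 ms) never overlap each
other, and at the shortest paired-pulse interval (50 ms) the first response
dies out before the second response's scoring window, so noiseless recovery
of amplitudes, latencies and the paired-pulse ratio is exact rather than
approximate — Gaussian tails would leak across windows at the 1e-3 level.
The latency draws sit inside the physiological 17–26 / 40–60 ms ranges.
Amplitudes follow a smooth unimodal depth profile (floor 0.25, Gaussian bump
peaking three quarters down the probe, mimicking the strongest deep-layer
responses) times a base amplitude (0.8 mV negative, 0.6 mV positive at the
peak channel) times condition scalings. Background noise is white Gaussian
low-passed at 100 Hz and rescaled per channel to `noise_sd` (default
0.05 mV): LFP background is dominated by slow components, and smooth noise
also keeps window-extremum statistics well behaved. Between-subject
variability is a log-normal amplitude factor (CV 0.1) and a ±0.05 jitter on
the paired-pulse ratio. When the sample rate supports the spike band
(≥ 20 kHz), biphasic ~1 ms transients are embedded at Poisson times whose
rate is the negative lobe shape scaled by 800 Hz at the peak channel, so
MUA has a known rate profile to recover. The stimulation protocol defaults
to the experimental one (15 repetitions, 5 s spacing, ISIs 50/100/200 ms);
tests and the acceptance script shorten the spacing to 1 s — the analysis
is windowed per trial, so spacing beyond the response duration only affects
runtime.

Condition scalings (negative scale, positive scale, paired-pulse ratio) are
direction-only — no numeric group amplitudes are available to calibrate
against — chosen once as: sham (1.0, 1.0, 0.8), stroke 5 d (0.25, 1.25,
0.6), stroke 30 d (0.6, 1.6, 0.5), robot+BoNT (0.85, 1.15, 0.7). They
encode: strong early damping of the transcallosal volley with partial
recovery by 30 days, enhanced late inhibition maximal at 30 days, deeper
paired-pulse depression after stroke, and normalization under combined
rehabilitation.

**Reaching.** The speed profile is a sum of `n` temporally separated Hann
bells (centres at `(k + ½)D/n`, half-width `0.35 D/n`, leaving zero-speed
gaps) whose integral is matched to the length of a circular out-and-back
loop of the configured extent. The circular geometry is deliberate:
constant curvature makes the chord-based sampled speed a monotone transform
of the injected speed, so the submovement count is exactly recoverable from
noiseless frames — a cusped or sharply curved turning point would dent the
sampled speed and split peaks. Real reach loops are thinner; only the
scalar ground-truth metrics are contractual. Because speed scale, duration
and geometry cannot all be fixed independently, the generator honours the
submovement count, duration and extent, and reports the realized peak speed
in the ground truth. Defaults (1 s, 12 mm extent, 120 Hz) are typical of
mouse single-pellet reaching.

**Platform.** `n` subthreshold raised-cosine force pulses (peak below the
0.2 N friction threshold, handle stationary) followed by one suprathreshold
pull with a smoothstep retraction from 10 mm to exactly zero; ground-truth
t-target is the completion time. Config validation enforces
`attempt_peak_force < friction_threshold ≤ pull_force`.

**Behavior.** Binomial tallies at configured rates; condition presets give
the pipeline realistic group differences (e.g. 5% → 25% impaired-limb foot
faults, asymmetry from impaired-limb use probability 0.5 → 0.3).

What the generators do *not* emulate: volume conduction consistent with a
true CSD source model (the evoked potentials are injected directly, so CSD
maps are checked for extremum location, not amplitude), electrode drift,
artifacts, correlated multi-channel noise, paw occlusion or lighting
variation in video, and any within-session learning. Passing tests
therefore demonstrate correct measurement of the quantities as defined, not
robustness to every failure mode of real recordings.

## Determinism and problem sizes

Every generator derives all randomness from one explicit seed through
`numpy.random.SeedSequence`, with per-subject parameter, noise and spike
streams separated so that changing a deterministic setting never perturbs
the other draws; identical (config, seed) is bit-identical output, and the
pipeline writes no timestamps so repeated runs produce identical files.
The test suite and the acceptance script use deliberately small problem
sizes — 15 trials at 1 s spacing and 1 kHz for LFP analyses (25 kHz only
where MUA needs the spike band), 100 repetitions for noisy-recovery rates,
10 subjects per group for direction effects, 100k replicates for the
Monte-Carlo power oracle — which are sufficient for the tolerances asserted
and keep a full run in the seconds-to-minutes range.
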