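# strokephys

Quantitative analysis pipeline for mouse stroke-rehabilitation studies that
combine laminar electrophysiology with motor behavior. After a focal cortical
stroke, the balance of interhemispheric connectivity shifts: optogenetic
stimulation of the healthy premotor cortex evokes, in the opposite (peri-lesional)
hemisphere, a weaker early negative field potential (direct transcallosal
excitation) and a stronger late positive one (disynaptic, GABA-B-mediated
inhibition), together with deeper paired-pulse depression. Rehabilitation
(robotic forelimb training combined with transient silencing of the healthy
hemisphere) normalizes these measures alongside motor recovery. `strokephys`
implements the measurements that quantify all of this:

- **Evoked field potentials** from 16-channel laminar probes: trial averaging,
  baseline-to-peak amplitude and latency of the early negative
  (17–26 ms) and late positive (40–60 ms) components, pooling of adjacent
  channels into Sup / Sup-Middle / Middle-Deep / Deep layer groups, and
  input/output curves against light intensity (with fibre-irradiance
  arithmetic).
- **Paired-pulse ratio** `PPR = A2/A1` at inter-stimulus intervals of
  50/100/200 ms, both responses measured peak-trough so the altered baseline
  before the second pulse cannot bias the ratio.
- **Inverse current source density** across cortical depth with the step
  method — the CSD is assumed piecewise-constant in slabs
  `[z_i − h/2, z_i + h/2]` on discs of radius `R`, the forward matrix
  `F[j,i] = 1/(2σ) ∫_slab [√(R² + (z_j − z′)²) − |z_j − z′|] dz′`
  is inverted per time sample — plus the classic second-spatial-difference
  estimate with Vaknin end-channel duplication. Maps are sign-inverted so
  current sinks are positive.
- **Multi-unit activity**: zero-phase 300–10,000 Hz band-pass, sliding-window
  RMS per trial, trial average, optional per-channel normalization to the
  first response peak.
- **Reaching kinematics** from 120 frames/s sagittal video: colour-contrast
  tracking of the green-painted paw, then ArcLen (path length), AUC (area
  enclosed by the reach-and-retract loop), Mean Speed (average tangential
  speed) and Smoothness (count of speed-profile peaks), with
  baseline-session normalization.
- **Robotic platform metrics**: the t-target (time to complete a 10 mm
  forelimb retraction) and attempts (force peaks that fail to overcome the
  0.2 N static friction without moving the handle).
- **Behavioral scores**: Gridwalk foot-fault percentage, cylinder-test
  asymmetry index `(unimpaired − impaired)/(total contacts)`, skilled-reaching
  error percentage, lesion volume (Σ section areas × 0.05 mm × spacing
  factor 6), and the study's power computation (two-sample t, noncentral t
  distribution: `d = 1.75`, `n = 5`/group, one-tailed α = 0.05 → power 0.81).
- A **synthetic-data generator** that produces seeded, ground-truth-labelled
  versions of every input — laminar recordings with injected component
  amplitudes/latencies and spike bursts, reach trajectories with a known
  submovement count, platform traces, behavioral tallies — with condition
  presets (sham, stroke at 5/30 days, robot+BoNT rehabilitation) that encode
  the reported effect directions.

The library is the primary interface; `examples/` contains one short script
per capability, and a thin `strokephys` command-line tool orchestrates
generate → analyze → summarize runs for scripted studies.

## Worked example

```bash
python examples/full_pipeline.py
```

generates five sham and five stroke-30d synthetic subjects, runs every
analysis stage and prints group summaries:

```
deep-layer FP amplitudes (mV, mean +/- SEM):
  sham       neg_amp_mV 0.725 +/- 0.049 (n=5)
  sham       pos_amp_mV 0.515 +/- 0.025 (n=5)
  stroke30d  neg_amp_mV 0.473 +/- 0.023 (n=5)
  stroke30d  pos_amp_mV 0.844 +/- 0.017 (n=5)

paired-pulse ratio at ISI 50 ms:
  sham       PPR 0.837 +/- 0.034
  stroke30d  PPR 0.484 +/- 0.026

behavior:
  sham       foot_fault_pct      6.80 +/- 1.36
  sham       asymmetry_index    -0.07 +/- 0.09
  sham       reach_error_pct    16.00 +/- 2.10
  stroke30d  foot_fault_pct     25.20 +/- 2.24
  stroke30d  asymmetry_index     0.36 +/- 0.04
  stroke30d  reach_error_pct    47.60 +/- 3.06
```

The stroke group shows the expected direction on every measure: smaller
early negative FP, larger late positive FP, lower PPR (stronger paired-pulse
depression), more foot faults, a positive forelimb-use asymmetry and more
reaching errors. The same pipeline is available from the shell
(`strokephys run-all --config study.yaml --out results/`), which writes tidy
per-subject CSV tables, group summaries and a JSON manifest; inferential
statistics are intentionally left to external tools.

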