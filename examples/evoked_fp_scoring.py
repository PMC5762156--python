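"""Score evoked field-potential components in a sham vs stroke cohort.

Generates noiseless synthetic laminar recordings for one sham and one
30-days-post-stroke subject, averages the evoked epochs, measures the early
negative and late positive FP components (baseline-to-peak) and pools them
into layer groups.  After stroke the transcallosal excitatory volley (early
negative wave) shrinks while the disynaptic inhibitory response (late
positive wave) grows.
"""

from strokephys import (CohortConfig, epoch_and_average, gen_evoked_lfp,
                        measure_fp_components, pool_layers)

for condition in ("sham", "stroke30d"):
    cfg = CohortConfig(condition=condition, n_subjects=1, seed=42,
                       noise_sd=0.0, n_trials=15, trial_spacing=1.0)
    subject = gen_evoked_lfp(cfg, [None])[0]
    avg = epoch_and_average(subject.recordings[None], (-50.0, 250.0))
    comp = measure_fp_components(avg)
    neg = pool_layers(comp.neg_amplitude)
    pos = pool_layers(comp.pos_amplitude)
    print(f"\n{condition}: negative peak at {comp.neg_latency[12]:.0f} ms, "
          f"positive at {comp.pos_latency[12]:.0f} ms")
    for layer in neg.mean:
        print(f"  {layer:12s} neg {neg.mean[layer]:.3f} mV   pos {pos.mean[layer]:.3f} mV")

print("\nDeep-layer negative FP falls and positive FP rises after stroke, "
      "the signature of weakened transcallosal excitation with enhanced "
      "interhemispheric inhibition.")
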