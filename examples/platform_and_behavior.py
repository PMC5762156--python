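"""Robotic-platform metrics, behavioral scores and lesion volume.

A platform trial is a synchronized force/position trace: subthreshold force
pulses that fail to overcome the 0.2 N static friction are 'attempts'; the
t-target is the time until the 10 mm retraction completes.  Behavioral
scores are simple percentages and a normalized asymmetry index.
"""

from strokephys import (LesionSections, PlatformConfig, asymmetry_index,
                        foot_fault_percentage, gen_behavior_counts,
                        gen_platform_trial, lesion_volume, platform_metrics,
                        reach_error_percentage)

trial, truth = gen_platform_trial(PlatformConfig(n_attempts=4, seed=8))
m = platform_metrics(trial)
print(f"platform: {m.n_attempts} attempts (injected {truth.n_attempts}), "
      f"t-target {m.t_target:.2f} s (retraction completed at {truth.t_target:.2f} s)")

counts, rates = gen_behavior_counts({"impaired": 0.25, "unimpaired": 0.05},
                                    p_impaired_use=0.30, n_events=50, seed=8,
                                    p_incorrect_reach=0.5)
print(f"gridwalk: {foot_fault_percentage(counts, 'impaired'):.1f}% impaired-limb "
      f"foot faults (rate injected {rates['p_fault_impaired']:.0%})")
print(f"cylinder: asymmetry index {asymmetry_index(counts):+.2f} "
      "(positive = preference for the unimpaired limb)")
print(f"reaching: {reach_error_percentage(counts):.1f}% incorrect grasps")

vol = lesion_volume(LesionSections(areas=[1.0, 1.2, 0.8]))
print(f"lesion volume from 3 sampled sections: {vol:.3f} mm^3 "
      "(sum of areas x 0.05 mm thickness x spacing factor 6)")
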