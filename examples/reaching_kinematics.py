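"""Skilled-reaching kinematics: tracking, speed profile, four metrics.

Generates a reach whose tangential speed is four separated submovement
bells, renders the green-painted paw onto video frames, tracks it back by
colour contrast, and computes ArcLen, AUC, Mean Speed and Smoothness.
Fragmented (less smooth) movements have more speed peaks.
"""

import numpy as np

from strokephys import (ReachConfig, gen_reach_trajectory, kinematic_metrics,
                        render_reach_frames, track_paw)

cfg = ReachConfig(n_submovements=4, seed=12)
traj, truth = gen_reach_trajectory(cfg)
m = kinematic_metrics(traj)
print("direct metrics from the generated trajectory:")
print(f"  ArcLen     {m.arc_len:7.2f} mm   (loop length {truth.arc_len:.2f} mm)")
print(f"  AUC        {m.auc:7.2f} mm^2 (enclosed area {truth.area:.2f} mm^2)")
print(f"  Mean Speed {m.mean_speed:7.2f} mm/s (truth {truth.mean_speed:.2f} mm/s)")
print(f"  Smoothness {m.smoothness:4d}       (injected submovements {truth.n_submovements})")

# round-trip through rendered video frames (2 px/mm calibration)
px_per_mm = 2.0
frames = render_reach_frames(traj.x * px_per_mm + 10, traj.y * px_per_mm + 20,
                             shape=(96, 96), radius=4.0)
tracked = track_paw(frames, mm_per_px=1.0 / px_per_mm, frame_rate=traj.frame_rate)
m2 = kinematic_metrics(tracked)
print(f"after render + colour-contrast tracking: ArcLen {m2.arc_len:.2f} mm, "
      f"Smoothness {m2.smoothness}")
print("The tracker reproduces the metrics from video alone; the submovement "
      "count survives the full render/track round trip.")
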