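"""Validate fixation quality from the two log streams of a session.

Fuses the frame and gaze logs, estimates and removes the eye tracker's
per-session calibration offset, then reports tracking error, pursuit
error, the peek rate, and gaze dispersion per trial epoch.
"""

import numpy as np

from crowdtrack import (
    ObserverModel,
    apply_offset_correction,
    detect_peeks,
    epoch_dispersion,
    estimate_calibration_offset,
    merge_logs,
    radial_rmse,
    simulate_session_logs,
)

# observer with a 0.64 deg radial calibration bias, as is typical
logs = simulate_session_logs(ObserverModel(), rng=np.random.default_rng(1))
timeline = merge_logs(logs.frames, logs.gaze, logs.geometry)

offset = estimate_calibration_offset(timeline)
print(
    f"calibration offset : ({offset.dx_deg:+.3f}, {offset.dy_deg:+.3f}) deg, "
    f"radial {offset.radial_deg:.3f} deg from {offset.n_samples} pre-onset samples"
)
timeline = apply_offset_correction(timeline, offset)

print(f"tracking RMSE      : {radial_rmse(timeline, 'cursor', 'pre'):.3f} deg (cursor vs crosshair)")
print(f"pursuit RMSE       : {radial_rmse(timeline, 'gaze', 'pre'):.3f} deg (gaze vs crosshair)")

peeks = detect_peeks(timeline)
print(f"peeks              : {peeks.percentage:.1f}% of {peeks.n_trials} trials "
      f"(gaze > {peeks.criterion_deg} deg from crosshair during the stimulus)")

print("\ngaze dispersion per epoch (deg):")
print(epoch_dispersion(timeline).round(3).to_string())
# Scatter is smallest while tracking (pre), grows during the stimulus
# (peeks), and is largest after stimulus offset, when the eyes saccade
# toward the now-absent target ("looking at nothing").
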