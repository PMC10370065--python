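"""Simulate one full testing session and inspect its two log streams.

A session is 140 trials: two blocks (test, retest), each randomly
interleaving 35 trials at -10 deg and 35 at +10 deg eccentricity.  The
simulator writes a 60 Hz frame log (crosshair, cursor, target) and a
100 Hz gaze log on a shared POSIX clock, just like the real apparatus.
"""

import numpy as np

from crowdtrack import ObserverModel, simulate_session_logs

logs = simulate_session_logs(ObserverModel(), rng=np.random.default_rng(1))

print(f"trials          : {len(logs.trials)}")
print(f"frame log rows  : {len(logs.frames)} (60 Hz)")
print(f"gaze log rows   : {len(logs.gaze)} (every 10 ms)")
print(f"restart rate    : {(logs.trials['restarts'] > 0).mean():.0%} of trials")
print(f"true peek rate  : {logs.trials['peeked_true'].mean():.1%}")
print("\nthresholds (one 35-trial staircase per block x meridian):")
print(
    logs.thresholds[["session", "meridian", "threshold_deg", "posterior_sd"]]
    .round(3)
    .to_string(index=False)
)
# The four thresholds estimate the same observer (true crowding distance
# 3.0 deg); their scatter shows the measurement noise of a 35-trial run.
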