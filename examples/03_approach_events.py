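"""Detect approach events in a tag session and inspect approaching angles.

An approach event is a downward crossing of the 50 cm personal-space
threshold; the approaching angle theta' samples the approacher's heading
angle in a look-back window, restricted to the 100-200 cm distance band.
"""

import numpy as np

from groupmotion import SimulationConfig, compute_velocity, pair_angle, pair_distance, simulate_tag
from groupmotion.approach import approach_angles, approach_matrix, detect_events

traj, truth = simulate_tag(SimulationConfig(n_agents=12, duration=40.0, seed=202))
traj = compute_velocity(traj)

dist = pair_distance(traj)
ang = pair_angle(traj)
events = detect_events(dist)
print(f"{len(truth.contacts)} tags happened; {len(events)} directed approach "
      f"candidates detected ({len(events) // 2} distance crossings)")

for window in ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0)):
    s = approach_angles(events, ang, dist, window=window)
    th = s.all_angles()
    frac = np.mean(th <= 20.0) if len(th) else float("nan")
    print(f"window {window[0]:.0f}-{window[1]:.0f} s before onset: "
          f"{len(th):4d} theta' samples, share <= 20 deg: {frac:.2f}")

s01 = approach_angles(events, ang, dist, window=(0.0, 1.0))
m = approach_matrix(s01, traj.individuals)
r, c = np.unravel_index(np.argmax(m.cells), m.cells.shape)
print(f"strongest directed pair in the 20-deg bin: {m.labels[r]} -> {m.labels[c]} "
      f"(normalized frequency {m.cells[r, c]:.2f})")
# Pursuit shows up as theta' mass near 0 deg concentrated in the last second
# before contact; two or three seconds earlier the approacher was not yet
# aiming at its target.
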