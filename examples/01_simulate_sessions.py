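"""Generate one rotation-regime and one tag-regime session and save them.

The rotation regime mimics a group running laps around the hall centre; the
tag regime mimics a pursuit game with role switches on contact (< 50 cm).
"""

from pathlib import Path

from groupmotion import SimulationConfig, simulate_rotation, simulate_tag, write_trajectory

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)

rot_cfg = SimulationConfig(n_agents=11, duration=40.0, seed=101)
tag_cfg = SimulationConfig(n_agents=12, duration=40.0, seed=202)

rot, rot_truth = simulate_rotation(rot_cfg)
tag, tag_truth = simulate_tag(tag_cfg)

write_trajectory(rot, out / "rotation.csv")
write_trajectory(tag, out / "tag.csv")
tag_truth.to_json(out / "tag.truth.json", tag.individuals)

print(f"rotation session: {rot.n_individuals} agents x {rot.n_frames} frames "
      f"({rot.duration:.1f} s), contacts logged: {len(rot_truth.contacts)}")
print(f"tag session:      {tag.n_individuals} agents x {tag.n_frames} frames "
      f"({tag.duration:.1f} s), contacts logged: {len(tag_truth.contacts)}")
print(f"files written to {out}/")
# Contacts are tags: frames where chaser and target came within 50 cm.
# The rotation regime has no pursuit, so it logs none.
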