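"""Full pipeline: compare a rotation-like class against a tag-like class.

Per-child normalized histograms for every index, pooled-variance t-tests per
bin with Bonferroni correction, and Hedges' g effect sizes.
"""

from pathlib import Path

from groupmotion import SimulationConfig, simulate_rotation, simulate_tag
from groupmotion.pipeline import PipelineConfig, render_outputs, run_pipeline

rot, _ = simulate_rotation(SimulationConfig(n_agents=11, duration=40.0, seed=101))
tag, _ = simulate_tag(SimulationConfig(n_agents=12, duration=40.0, seed=202))

out = Path("scratch/examples/report")
bundle = run_pipeline(
    PipelineConfig(class_a=[rot], class_b=[tag], label_a="rotation-like",
                   label_b="tag-like", out_dir=out)
)
render_outputs(bundle, out)

c50 = bundle.comparisons["distance"][0]       # the 50 cm bin
cm1 = bundle.comparisons["momentum"][-1]      # the momentum bin 1
print(f"distance 50 cm bin: mean {c50.mean_a:.4f} vs {c50.mean_b:.4f}, "
      f"t({c50.df}) = {c50.t:.3f}, Bonferroni p = {c50.p_corrected:.3g}, "
      f"g = {c50.g:.3f}")
print(f"momentum bin 1:     mean {cm1.mean_a:.3f} vs {cm1.mean_b:.3f}, "
      f"t({cm1.df}) = {cm1.t:.3f}, Bonferroni p = {cm1.p_corrected:.3g}, "
      f"g = {cm1.g:.3f}")
print(f"tables and figures in {out}/")
# Negative t in the 50 cm bin: the tag-like class spends more time within
# touching distance.  Positive t in momentum bin 1: the rotation-like class
# shows the stronger collective rotation.  These are the two directions the
# pipeline is designed to detect.
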