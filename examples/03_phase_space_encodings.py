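"""Encode one cardiac cycle into its three phase-space images.

RP marks pairs of delay-embedded states closer than epsilon (chosen for
a 10% recurrence rate), GASF is the cosine-sum Gramian of the polar
angles, MTF projects quantile-bin transition probabilities onto the
time-time plane.  All three are rendered as 224x224 planes in [0, 1].
"""

import numpy as np

from mcgscreen import synthetic
from mcgscreen.embedding import delay_embed, select_epsilon
from mcgscreen.encoders import gasf, mtf, recurrence_plot, to_image
from mcgscreen.pipeline import PipelineConfig, preprocess_cohort

cfg = PipelineConfig()
cohort = synthetic.generate_cohort(1, 1, 8, seed=5)
cycles = preprocess_cohort(cohort, cfg)
cycle = cycles[0]

traj = delay_embed(cycle.x, m=3, tau=4)
eps = select_epsilon(traj, 0.10)
rp = recurrence_plot(traj, eps)
g = gasf(cycle.x)
mt = mtf(cycle.x, Q=8)

print(f"trajectory: {traj.points.shape[0]} points in R^{traj.points.shape[1]}, epsilon={eps:.4f}")
print(f"RP   {rp.R.shape}, recurrence density {rp.R.mean():.3f} (target 0.10 plus the diagonal)")
print(f"GASF {g.G.shape}, entries in [{g.G.min():.2f}, {g.G.max():.2f}], symmetric")
print(f"MTF  {mt.field.shape}, entries in [{mt.field.min():.2f}, {mt.field.max():.2f}], "
      f"{np.count_nonzero(mt.transition.sum(axis=1))} occupied states of {mt.Q}")
for matrix, name in ((rp, "RP"), (g, "GASF"), (mt, "MTF")):
    img = to_image(matrix, name)
    print(f"{name:4s} image plane {img.pixels.shape}, range "
          f"[{img.pixels.min():.2f}, {img.pixels.max():.2f}]")
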