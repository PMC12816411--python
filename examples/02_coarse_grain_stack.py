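"""Watch an image dissolve: the coarse-graining stack step by step.

Builds a checkerboard, low-passes it through the 10-step geometric radius
schedule, and prints how much pixel energy survives each step. The PNG
sequence (written under scratch/) shows the board blurring into its mean.
"""

from pathlib import Path

import numpy as np

from mssc import FixtureSpec, build_stack, generate, make_schedule
from mssc.coarse_grain import export_stack_pngs

g = generate(FixtureSpec("checkerboard", 128, {"period": 16})).channels["L"]
sched = make_schedule(128, 10)
stack = build_stack(g, sched)

print("step  cutoff_px   mean squared intensity")
for k, grid in enumerate(stack.grids):
    radius = "(original)" if k == 0 else f"{sched.radii[k - 1]:9.2f}"
    print(f"{k:4d}  {radius:>10}  {np.mean(grid.pixels ** 2):.6f}")

out = Path("scratch/stack_demo")
paths = export_stack_pngs(stack, out)
print(f"\nWrote {len(paths)} PNGs to {out}/ — P_0 is the original, P_10 its mean.")
print("Energy only ever decreases: each step is an orthogonal projection.")
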