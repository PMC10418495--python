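"""Bubble statistics on prescribed bond-state trajectories.

Random Bernoulli masks have a known closed form for the isolated broken
pair (open state): an interior position is a lone break with probability
p(1-p)^2.  This script checks the generator and the run-length machinery
against that expectation.
"""

import numpy as np

import dnabubbles as db
from dnabubbles.bubbles import occupancy_fractions

p, n, m = 0.3, 5000, 40
traj = db.generate_mask_series(n, m, law="random", p=p, seed=2)
qs = np.array([occupancy_fractions(traj.broken[j])["OS"] for j in range(m)])
expected = p * (1 - p) ** 2
print(f"mean OS occupancy over {m} masks: {qs.mean():.5f}")
print(f"Bernoulli closed form p(1-p)^2:  {expected:.5f}")
print(f"standard error of the mean:      {qs.std(ddof=1) / np.sqrt(m):.5f}")

mask = traj.broken[0]
runs = db.decompose_runs(mask)
print(f"first mask: {int(mask.sum())} broken pairs in {len(runs)} bubbles; "
      f"longest = {max(r.length for r in runs)} bp")
print(
    "Each bubble is a maximal run of broken pairs; occupancy fractions per\n"
    "size class sum to the broken share of the sequence."
)
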