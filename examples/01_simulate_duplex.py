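"""Integrate a small duplex and measure bubble occupancy.

Builds a 24-bp synthetic duplex with realistic regional A-T content,
integrates the torsional dynamics under periodic forcing with the
printed-sign ("literal") coupling, and prints the occurrence probability P
of each bubble size class at one critical energy.
"""

import dnabubbles as db
from dnabubbles.dynamics import ModelOptions

spec = db.SyntheticSpec(n=24, at_fractions={"I": 0.551, "II": 0.530, "III": 0.709}, seed=7)
duplex, partition = db.generate_sequence(spec)
print(f"sequence ({duplex.n} bp): {duplex.bases}")

mech = db.build_pair_mechanics(
    duplex, db.default_base_mechanics().with_uniform_ecr(0.250e-22)
)
traj = db.simulate(
    mech,
    db.ForcingSpec(),  # F0 = 0.526e-22 N*m, omega = 0.4e12 1/s
    db.IntegrationSpec(T=2e-10, tau=1e-13),
    ModelOptions(mode="literal"),
)
print(f"samples recorded: {traj.samples}, broken-pair share overall: {traj.broken.mean():.4f}")

for group, p in db.occupancy_probabilities(traj).items():
    print(f"  P[{group}] = {p:.4f}")
print(
    "P is the time-averaged fraction of base pairs lying in bubbles of each\n"
    "size class (OS = lone open pair, group1 = 2-4 bp, ... group4 = >30 bp)\n"
    "at critical energy 0.250e-22 N*m."
)
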