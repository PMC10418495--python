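"""Scan every single-deuterium substitution across a small energy grid.

Each position of a 16-bp duplex in turn receives one 2H-for-1H replacement
(kD = 1.05: the bond constant and critical energy at that pair scale up by
5%), and each variant is re-simulated at every critical energy.  The output
compares the all-protium baseline P0 with the extremes over positions.
"""

import dnabubbles as db
from dnabubbles.dynamics import ModelOptions

spec = db.SyntheticSpec(n=16, at_fractions={"I": 0.5, "II": 0.5, "III": 0.7}, seed=11)
duplex, _ = db.generate_sequence(spec)
print(f"sequence: {duplex.bases}")

grid = db.EnergyGrid(values=(0.250, 0.400))
profile = db.scan_positions(
    duplex,
    db.default_base_mechanics(),
    db.ForcingSpec(),
    db.IntegrationSpec(T=2e-10, tau=1e-13),
    grid,
    kD=1.05,
    options=ModelOptions(mode="literal"),
)

for energy in grid.keys:
    print(f"Ecr = {energy}e-22 N*m")
    for group in db.GROUP_ORDER:
        p0 = profile.p0(energy, group)
        pmax, pmin, argmax, argmin = db.extrema(profile, energy, group)
        print(
            f"  {group:7s} P0={p0:.4f}  Pimax={pmax:.4f} at {sorted(argmax)[:3]}  "
            f"Pimin={pmin:.4f} at {sorted(argmin)[:3]}"
        )
print(
    "Pimax > P0 marks substitution sites that promote bubbles of that size;\n"
    "Pimin < P0 marks sites whose stronger deuterium bond suppresses them."
)
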