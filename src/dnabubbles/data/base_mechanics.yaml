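# Default mechanical coefficient table for the torsional pendulum-chain
# duplex model.
#
# Provenance: these numbers are representative values drawn from the
# published literature on Yakushevich-family torsional DNA models (rigid
# nitrogen bases rotating about the sugar-phosphate backbone).  They are
# shipped so the model runs out of the box on synthetic sequences; they are
# NOT calibrated to any particular gene.  Every entry can be overridden via
# a user config file with the same keys.
#
# Units are SI unless a scale is stated:
#   inertia      kg*m^2       rotational inertia I of each base
#   radius       m            distance R from base centre of inertia to backbone
#   torsion.K    N*m          backbone torsional constant (uniform default;
#                             per-letter keys A/T/G/C are also accepted)
#   dissipation  N*m*s        environmental drag beta per base
#   bond         N/m          hydrogen-bond elastic constant k12 per pair kind
#   ecr          (x energy_scale) N*m   protium critical energy per pair kind
#
# units.energy_scale lets ecr (and configs reusing this convention) be
# written in the conventional 1e-22 N*m units.
units:
  energy_scale: 1.0e-22
inertia:
  A: 7.61e-44
  T: 4.86e-44
  G: 8.22e-44
  C: 4.11e-44
radius:
  A: 5.8e-10
  T: 4.8e-10
  G: 5.7e-10
  C: 4.7e-10
torsion:
  K: 2.35e-18
dissipation:
  A: 4.25e-34
  T: 4.25e-34
  G: 4.25e-34
  C: 4.25e-34
bond:
  AT: 0.062
  GC: 0.096
ecr:
  AT: 0.400   # x 1e-22 N*m
  GC: 0.400
kD: 1.05
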