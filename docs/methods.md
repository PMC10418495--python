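# Methods

## The mechanical model

The duplex is a pair of coupled torsional pendulum chains.  Pair *i*
carries one base on each chain; base (j, i) has rotational inertia I_ji,
sits at distance R_ji from its sugar–phosphate backbone, and deflects by
the angle φ_ji(t) (counterclockwise, radians).  Three torques act on it:

* **Backbone elasticity.**  K_ji(φ_j,i−1 − 2φ_ji + φ_j,i+1) in the chain
  interior; the end pairs see only their single neighbour,
  K(φ_j,2 − φ_j,1) and K(φ_j,n−1 − φ_j,n).  This term also stands in for
  base stacking; it needs n ≥ 2.
* **Hydrogen-bond coupling** to the complementary base, with elastic
  constant k₁₂,ᵢ, gated by the bond indicator δᵢ (1 intact, 0 broken).
* **Environment.**  −β_ji φ̇_ji + F₀ cos ωt: viscous dissipation plus a
  spatially uniform periodic drive applied identically to every base on
  both chains (the minimal reading of an unspecified spatial profile; a
  future per-base profile would slot into the same term).

The closed duplex is (φ₁, φ₂) = (0, π) with zero velocities and all δ = 1;
that state is the integrator's initial condition.

### Sign conventions: `conservative` vs `literal`

Two coupling conventions are implemented because the commonly printed form
of these equations is not derivable from any single interaction potential:
the relative-rotation torque k₁₂R₁R₂ sin(φ₁ − φ₂) appears with the *same*
sign on both chains, which makes the coupling circulatory
(non-conservative).

* `conservative` (library default): both chains' bond torques are the
  exact negative gradients of the explicit potential
  V_i = g_i k₁₂ [(R₁+R₂)(R₁(1−cos φ₁) + R₂(1+cos φ₂)) + R₁R₂(1+cos(φ₁−φ₂))],
  so (0, π) is a true energy minimum and, with β = F₀ = 0, total mechanical
  energy is conserved up to RK4 truncation (audited in the tests).
* `literal` (`model.mode: literal`): reproduces the printed signs verbatim.
  The circulatory term pumps energy; under the default forcing
  (F₀ = 0.526×10⁻²² N·m, ω = 0.4×10¹² s⁻¹) amplitudes grow to several
  radians by t ≈ 1.2×10⁻¹⁰ s and bond energies sweep through the whole
  critical-energy grid.  This is the regime in which bubbles actually form
  at the stated forcing: in conservative mode the bond-stretch coordinate
  is driven only through the inertia mismatch of the two bases and, for
  any plausible coefficient table we examined, never reaches
  0.250×10⁻²² N·m within the default horizon.  End-to-end demonstrations,
  the examples and the scaled-down pipeline therefore run in literal mode;
  the conservative mode is the well-posed reference for numerical audits
  (gradient checks, energy conservation, convergence order).

δ-gating: by default δ gates *both* bond-torque terms (a broken pair is
mechanically decoupled); `model.delta_gates_both: false` restores the
printed placement, where δ gates only the backbone-referenced term.

### Bond breaking and restoring

The break test uses the bond-stretch energy
E_i = k₁₂ R₁ R₂ (1 + cos(φ₁ − φ₂)) — the part of the pair potential that
vanishes at the closed state and directly measures how far the pair has
twisted out of register (`model.break_energy: full` adds the
backbone-referenced terms).  After each completed RK4 step:

* δᵢ: 1 → 0 where Eᵢ > E_cr,ᵢ;
* δᵢ: 0 → 1 where Eᵢ < E_cr,ᵢ;
* Eᵢ exactly equal to E_cr,ᵢ changes nothing (strict inequalities prevent
  chatter).

δ is frozen within the four RK4 stages; sub-step event location is out of
scope.  A single ²H substitution at pair *i* multiplies k₁₂,ᵢ and E_cr,ᵢ
by k_D (default 1.05) and touches nothing else — deuteration stiffens the
bond but the model does not alter inertia or drag.

## Parameters

| parameter | meaning | unit | default | note |
|---|---|---|---|---|
| I (A/T/G/C) | base rotational inertia | kg·m² | 7.61/4.86/8.22/4.11 ×10⁻⁴⁴ | representative of published torsional-model tables |
| R (A/T/G/C) | base-to-backbone distance | m | 5.8/4.8/5.7/4.7 ×10⁻¹⁰ | id. |
| K | backbone torsional constant | N·m | 2.35×10⁻¹⁸ | uniform; per-letter override supported |
| β | environmental drag | N·m·s | 4.25×10⁻³⁴ | uniform across letters; β = 0 allowed for audits |
| k₁₂ (AT/GC) | H-bond elastic constant | N/m | 0.062 / 0.096 | A–T and T–A share a value, likewise G–C/C–G |
| E_cr | critical energy | N·m | grid 0.250…0.600 ×10⁻²² step 0.050 | swept; one value applies to every pair at a grid point |
| k_D | deuterium/protium bond-strength ratio | — | 1.05 | scales k₁₂ and E_cr at the substituted pair only |
| F₀, ω | drive amplitude, frequency | N·m, s⁻¹ | 0.526×10⁻²², 0.4×10¹² | uniform over the duplex |
| T, τ | horizon, step | s | 3×10⁻¹⁰, 10⁻¹⁴ | m = T/τ = 30,000 samples at stride 1 |

The per-base table is *not* calibrated to any specific gene: quantitative
work on a real sequence should override it via config
(`units.energy_scale` lets E_cr and F₀ be quoted in 10⁻²² N·m units).
Coordinates are 1-based inclusive everywhere at the API surface; the FASTA
strand is chain 1 and its complement chain 2 (a fixed convention — the
physics is symmetric under the swap).

## Bubble statistics

A bubble is a maximal run of consecutive broken pairs on the linear duplex
(no circularity; runs touching the ends are ordinary runs).  Size classes:
open state OS = 1 bp, group 1 = 2–4 bp (small), group 2 = 5–10 bp
(metastable), group 3 = 11–30 bp (large), group 4 > 30 bp (very large).
For each recorded sample t_j = jτ (j = 1…m; the t = 0 state is not a
sample), q_j of a class is the summed length of runs falling in the class
divided by n, and P is the arithmetic mean of q_j over samples.  Group
occupancies are computed directly from run lengths, never by enumerating
every possible length.

A useful monotone statistic: the *tail* occupancy (pairs in runs of length
≥ L) can only decrease when a mask shrinks, e.g. when the same recorded
trajectory is re-thresholded at a higher E_cr.  Per-class occupancies are
**not** monotone under re-thresholding — shortening a large run moves its
mass into smaller classes — so monotonicity checks in the test suite use
the tail form.

## The substitution scan

For each grid energy: one all-protium baseline simulation (reported as
position 0), then one simulation per substitution position with
IsotopeSpec(i, k_D).  The grid value replaces E_cr^H for every pair at that
grid point (the sweep treats E_cr as a single scanned parameter; the
kind-specific `ecr.AT`/`ecr.GC` table entries serve runs outside a sweep),
and the substituted pair uses k_D·E_cr^H.  Energies are carried as exact
decimal strings ("0.250") in all tables and files; SI floats exist only
inside the dynamics.  The scan is deterministic and embarrassingly
parallel over (energy, position); a TSV checkpoint records each completed
unit so an interrupted full-gene scan (hours at n = 980 × 8 energies)
resumes to a bit-identical table.

## The modified BJ classification

Per (energy, class), with Pimax/Pimin the extremes of Pᵢ over positions and
P₀ the baseline:

* **Maximum range** (needs Pimax > P₀ ≥ Pimin ≥ 0): cut at
  Pimax − (Pimax−Pimin)/10 if that still clears the midpoint
  P₀ + (Pimax−P₀)/2, else at Pimax − (Pimax−P₀)/4; members are positions
  with Pᵢ at or above the cut (ties included — all comparisons non-strict).
* **Minimum range** (needs Pimax ≠ Pimin > 0): symmetric cuts
  Pimin + (Pimax−Pimin)/10 or Pimin + (P₀−Pimin)/4.
* **Closed states** (Pimin = 0): members are the positions with Pᵢ = 0 and
  the *differentiated count* n_CS·(1 − (n_CS/n)²) is reported as
  effective_nmin alongside the raw tally — it approaches the raw count
  when closed states are rare and vanishes when every position is closed,
  damping false positives.  The correction's printed typography admits a
  second parenthesization, n_CS·(1 − n_CS/n)², available via
  `alt_closed_parse`; both vanish at the all-closed boundary and the
  minimal-parenthesization reading is the default.

Degenerate cases: a flat profile (Pimax = Pimin > 0) defines no range;
if P₀ < Pimin (every substitution raised occupancy) or P₀ ≥ Pimax, the
Maximum branch conditions fail and the range is empty.  Summaries report
raw member counts per region with A–T tallies; percentages are rounded
half-away-from-zero to one decimal at presentation only.  The thresholds
are scale-equivariant: rescaling every Pᵢ and P₀ by c > 0 rescales the
cuts and leaves membership unchanged.

## Association statistics

The 2×2 Yates statistic is the shortcut
N(|ad − bc| − N/2)²/(N_A N_B N_S N_F) with the conventional clamp at
|ad − bc| ≤ N/2 (the uncorrected shortcut inflates near-null tables; the
literal unclamped value stays available for audit).  The 3×2 test is the
Pearson statistic (ν = 2) with three pairwise Yates follow-ups carrying
Bonferroni-tripled p-values capped at 1.  Kruskal–Wallis and Spearman wrap
scipy with the degenerate cases pinned: all-identical data gives H = 0,
p = 1; zero rank variance raises.  Which margins populate a given
comparison (range counts vs region sizes) is a modelling choice: the
report command documents and uses the count-vs-region-size recipe and
skips a contrast whenever an aggregate count exceeds its region size
(those margins are undefined).

## Synthetic data

The generators define the test conditions.  `generate_sequence` draws a
duplex with prescribed per-region A–T fractions (defaults mirror a real
980-bp gene's three-part layout: promoter 1–49 at 55.1%, coding 50–619 at
53.0%, termination 620–980 at 70.9%; shorter n scales the boundaries
proportionally); the realized fraction is exact to rounding (±1 pair).
`generate_mask_series` produces prescribed bond trajectories — constant,
alternating, or i.i.d. Bernoulli(p) — whose run-length statistics have
closed forms (interior lone-break probability p(1−p)²).  Both are pure
functions of (spec, seed); there is no global random state, and the
dynamics themselves contain no randomness at all.

What the synthetic data does *not* emulate: real genes have correlated
base order (codon structure, repeats), and Bernoulli masks lack the strong
temporal and spatial correlation of mechanically generated bubbles.
Passing tests therefore validate the statistics and bookkeeping machinery,
not the biological realism of any particular coefficient table.

## Numerical choices and problem sizes

* Classic RK4, fixed step; observed convergence order 4.0 ± 0.01 on smooth
  two-pair configurations (Richardson triple).
* Equilibrium is preserved to the floating-point noise floor
  (< 10⁻¹⁶ rad over 10⁴ steps at n = 32 without forcing).
* Test and demonstration runs use scaled-down sizes chosen to exercise
  every code path at interactive cost: n = 16–32 duplexes, m = 2,000 steps
  at τ = 10⁻¹³ s (T = 2×10⁻¹⁰ s, so the literal-mode growth crosses the
  energy grid within the horizon), and 2-energy grids for scans.  Full
  paper-scale runs (n = 980, 8 energies, m = 30,000) use the same code via
  the checkpointed scan.
* Tie-breaks: bond update ties leave δ unchanged; BJ threshold ties are
  included in the range; duplicate grid energies are rejected (the grid
  must be strictly increasing).

## Limitations

* The shipped coefficient table is representative, not gene-calibrated;
  absolute P values depend strongly on it.
* The literal mode is non-conservative by construction; its amplitudes are
  bounded only by dissipation and the horizon.  It exists to reproduce the
  printed dynamics, not as a physical energy model.
* No thermal noise (the drive is deterministic), no adaptive stepping, no
  sub-step bond-event location, no helicoidal/stacking terms beyond K, no
  multi-site substitutions, and no modelling of which of a pair's two or
  three hydrogen bonds carries the ²H (the single k_D factor absorbs it).
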