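# Methods

## Problem and representation

confplan searches for energetically feasible transitions between protein
backbone conformations. A conformation is parameterized purely by the
backbone torsions (phi, psi) of each residue; bond lengths, bond angles and
the peptide torsion omega are fixed at idealized values, so the degrees of
freedom are 2·(residues) − 2 angles (phi of residue 1 and psi of the last
residue are undefined). Cartesian coordinates for the N/CA/C atoms are
derived by sequential natural-extension placement (each atom positioned
from the previous three via bond length, bond angle, torsion) in a
canonical frame: residue 1's N at the origin, CA on +x, C in the xy-plane.
Keeping every conformation in this frame makes the build→extract→build
round trip exact and lets all moves be purely torsional.

Idealized geometry defaults (configurable through `IdealGeometry`):
N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles N–CA–C 111.2°,
CA–C–N 116.2°, C–N–CA 121.7°; omega 180° (trans). These are standard
published idealized peptide values; any fixed set works as long as building
and extraction use the same constants. Angles are degrees at every API
boundary, wrapped to (−180, 180], IUPAC torsion sign; residue indices are
1-based.

## Energy model

The built-in score is a soft-sphere clash energy:
E = Σ k·(σi + σj − d)² over non-excluded atom pairs with d < σi + σj,
with σ = 1.7 Å for all backbone atoms, k = 1 (score units/Å²), and an
8 Å neighbor cutoff. Pairs within 4 covalent bonds along the backbone are
excluded. The exclusion depth matters: with a uniform 1.7 Å radius, an
ideal α-helix (phi, psi ≈ −57, −47) has C(i)–N(i+2) contacts (4 bonds
apart) at ≈3.27 Å < 2σ, so a depth-3 exclusion would assign every helix a
positive clash score and no helical structure could ever be "clash-free".
Depth 4 (excluding 1-5 pairs) makes regular secondary structure score zero
while still penalizing genuine steric overlap.

The energy interface is pluggable: any deterministic
`Conformation -> float` callable can replace the built-in score. The
planner only ever compares scores against a user-chosen threshold;
feasibility uses ≤ (boundary included). The score has no thermodynamic
interpretation; thresholds are experiment inputs, not physical constants.

Minimization is greedy derivative-free coordinate descent over torsions:
for each defined angle in the subset try ±step (default 5°), keep the best
non-worsening change, halve the step after a pass with no improvement.
Gradient-free keeps the energy interface fully pluggable. Energy never
increases; the procedure is deterministic.

## Moves

Four operators, all torsional (ideal geometry is preserved exactly):

- **Dihedral perturbation** — each defined torsion of a subset changes by
  an independent uniform draw from [−Δ, +Δ]; Δ defaults to 10°, keeping
  acceptance rates useful while still making progress.
- **Loop sampling** — record the anchor atoms (N, CA, C of the residue just
  past the loop), draw all loop torsions uniformly at random, then close
  back onto the recorded anchors with CCD. The chain outside the loop is
  untouched; everything downstream rides rigidly with the anchor residue.
  For a collection of loops the closures run sequentially in random order
  and the move succeeds only if all succeed. Note the closure tolerance is
  measured at the anchors: a rotational residual of ~0.05 Å over the anchor
  triad can translate into Å-scale displacement far downstream (lever-arm
  amplification). This is an inherent property of closing onto a 3-atom
  pose; analyses that need tight downstream control should tighten `tol`.
- **Rigid-body displacement** — sample a small rigid transform of the
  anchor targets (translation ≤ 1 Å, rotation ≤ 5° about the anchor
  centroid) and CCD-close the loop onto the transformed targets, moving the
  entire downstream domain as a rigid body.
- **Minimization** — whole-protein coordinate descent (15 passes by
  default); applied rarely because it is by far the most expensive move.

### CCD closure

Cyclic coordinate descent sweeps the loop torsions in chain order; each
torsion is rotated by the closed-form angle minimizing the summed squared
distance of the three anchor atoms to their targets. Success means RMS
anchor deviation ≤ tol (default 0.08 Å) within the sweep budget (default
200), with an early exit when a full sweep improves the deviation by less
than 10⁻⁴ Å (greedy CCD often stalls in a local minimum, and a cheap exit
keeps planner iterations fast; the success criterion is unchanged).

A caveat users should know: greedy CCD on *random* loop-closure problems
converges slowly. Measured on 100 seeded feasible problems (loop lengths
5–9, random start torsions, targets recorded from another random
conformation of the same loop): 42% close within 200 sweeps, 87% within
1000, 99% within 5000 — consistent with published CCD benchmarks, which
allow thousands of iterations. Over-relaxation, sweep-order variants,
two-stage position-then-pose closure and restart schemes were evaluated and
do not materially beat plain CCD at a fixed sweep budget. The planner is
insensitive to this: a failed closure simply returns the input and the move
is rejected, so loop moves act as a rejection sampler.

## Schema

A schema is a weighted list of residue subsets, each with its own
distribution over move kinds and optional per-move parameter overrides.
Subsets may overlap and need not be contiguous. Sampling is two-stage:
subset by selection probability, then move kind from the subset's
distribution.

The automatic schema derives from a per-residue secondary structure
annotation (H/E/L): one subset per maximal same-label run, with sampling
weights 1.0 (loop), 0.2 (sheet), 0.1 (helix); a whole-protein subset is
selected with fixed probability 0.09 and the remaining 0.91 is split over
the elements proportionally to weight. Element subsets draw the three
perturbation moves with equal probability — loop and rigid-body moves apply
to helix/sheet runs too, so secondary structure can dissolve. The
whole-protein subset's internal distribution is {minimize 1/9, dihedral
8/27, loop 8/27, rigid 8/27}: this makes the unconditional minimization
rate exactly 0.09 × 1/9 = 1% while keeping rare whole-protein perturbations
available. (The 9% subset-selection and 1% minimization frequencies are
both design targets; this split is the unique simple distribution
satisfying both at once, and it is configurable.)

Expert schemas load from YAML (`{id, residues: "45-55,87-91",
probability, moves, params}` entries, 1-based inclusive ranges). Listed
probabilities that do not sum to 1 are renormalized with a warning —
published expert configurations sometimes print values summing to 0.99.

## Planner

The planner grows a tree of feasible conformations, KPIECE-style. Sampling
density is estimated in a random 2D projection: a conformation's defined
torsions map to the 2n-vector (cos θ1, sin θ1, …, cos θn, sin θn), which is
projected by a fixed 2×2n matrix — Gaussian entries, row 1 normalized, row
2 Gram–Schmidt-orthogonalized and normalized — onto a plane, then binned on
a regular grid. A non-empty cell is *exterior* if any of its 8 neighbors is
empty, else *interior*. Each iteration: (1) pick a class — exterior with
probability p_ext = 0.75 ("heavily biased" toward the frontier), falling
back if a class is empty — and a cell within it with probability ∝
1/occupancy; (2) pick a conformation uniformly from the cell; (3) apply a
schema move (for loop/rigid moves the subset's contiguous runs, clipped to
residues 2..n−1, are the closable loops); (4) accept iff energy ≤
threshold. Accepted nodes record parent, generating (subset, move), energy
and grid placement, so any node's root path is a candidate transition.

Cell selection uses inverse occupancy only; selection counts and cell age
(refinements in some planner implementations) are deliberately not part of
the weight.

Directed mode: with probability goal_bias = 0.05 the move is replaced by a
bounded interpolation step — every defined torsion moves toward the goal
along the shortest angular arc, at most Δ = 10° each. The stopping metric
is mean wrapped absolute torsion difference to the goal (default tolerance
5°); CA-RMSD is available alongside from the analysis module. Grid cell
size defaults to an automatic heuristic: project the start plus 100 random
whole-chain perturbations, take the larger axis span, divide by 10.

Determinism: one `numpy` Generator seeded from the config drives cell
selection, node selection, schema sampling and all move randomness; the
projection seed derives from the same stream. Identical (start, schema,
config) reproduce the tree node for node.

The search is single-process; independent runs with different seeds can be
merged offline by concatenating archives (no shared density state). Hot
paths — CCD sweeps, chain building, the pair-sum energy — are numba-compiled.

## Synthetic test systems

The toybox generates transition problems with known mechanisms, emulating
the two canonical motion classes of real transition benchmarks at desk
scale:

- **Hinge** (default 8-5-8 = 21 residues): helix–loop–helix around
  (−57, −47) helical and (−120, 120) extended anchors with ±8° jitter; the
  goal shifts every central-loop torsion by a hinge delta (default 40°),
  swinging the second helix as a rigid arm. Both endpoints are verified
  clash-free; a clashing draw is rejected and redrawn (≤10 attempts).
- **Tri-loop** (default 4 blocks of 6 + 3 loops of 4 = 36 residues):
  alternating helical blocks and loops; domain A = blocks 1 and 3, domain
  B = blocks 2 and 4. The goal rotates domain B by 5° about the structure
  centroid, realized by closing loop 1 onto rotated anchors, loop 2 back
  onto the original anchors, loop 3 onto rotated anchors — so all three
  loops must change coordinately, while block torsions are bit-identical
  between the states. CCD stalls during generation are handled by random
  restarts and, if needed, a fresh rotation axis; generation fails loudly
  otherwise. The rotation pivot sits at the structure centroid to minimize
  the lever arm at every loop (a distant pivot makes the third closure
  frequently unreachable).
- **Decoys**: copies with independent Gaussian torsion noise (wrapped),
  for landscape and density fixtures.

What the toys do *not* model: side chains, sequence-dependent sterics,
realistic loop length distributions, energetics beyond excluded volume.
Passing the end-to-end tests shows the machinery (schema sampling, closure,
density-biased growth, goal bias) works as specified — not that the default
energy model would rank real protein conformations correctly.

## Analysis

- **Torsional activity**: D_i = Σ_k |wrap(φ_{i,k+1} − φ_{i,k})| +
  |wrap(ψ_{i,k+1} − ψ_{i,k})| along a root-to-node path; wrapped
  differences, so a 179° → −179° step counts 2°. Additive under path
  concatenation; identifies the residues doing mechanical work.
- **PCA landscape**: conformations are Kabsch-superposed onto a reference
  (CA atoms by default; configurable), the full backbone coordinates
  flattened, mean-centered and projected onto the top two principal axes.
  Superposition removes global placement, so the embedding is invariant (up
  to component sign) to rigid transforms of the inputs. Degenerate input
  (zero variance) maps to the origin with explained variance reported as 0.
- **Goal-distance trace**: per-step CA-RMSD to a goal after optimal
  superposition.
- **Basin centroid**: circular mean of each torsion over the selected
  low-energy conformations, rebuilt through the kinematics — Cartesian
  averaging would break covalent geometry; circular means in torsion space
  keep the result ideal.

## Numerical choices and degenerate inputs

- Angle wrap is (−180, 180]; −180 maps to +180. NaN is the undefined-torsion
  sentinel and passes through wrapping.
- Torsion extraction raises (naming the residue) on collinear quadruples.
- Kabsch superposition recomputes the RMSD from the aligned residuals
  rather than trusting the singular-value residual, which loses ~√ε
  precision near zero.
- PDB I/O (via biotite) supports single-chain N/CA/C files; insertion codes
  are rejected, multi-model files use model 1 with a warning. Coordinates
  survive a write/read round trip to the format's 10⁻³ Å; torsions
  correspondingly to ~0.1°.
- `select_cell` falls back to the other class when exterior or interior is
  empty; a single-cell grid always returns that cell.
- Empty subsets, too-short loops (< 3 interior residues) and out-of-range
  loops fail fast with diagnostics rather than raising mid-search.

## Problem sizes used in tests

The test and acceptance workloads use the 21-residue hinge toy (directed
runs up to 20,000 iterations; mode comparisons at a 5,000-iteration budget
over 10 seeds), 36-residue tri-loop problems, 100-chain kinematic round
trips up to 100 residues, and 10⁵-draw sampling statistics. These sizes
were chosen so the full suite exercises every code path at statistical
resolution sufficient for the asserted tolerances.

## Known limitations

- Greedy CCD needs thousands of sweeps for near-certain closure of random
  loop problems; at the default 200-sweep budget closure acts as a
  rejection sampler (see above).
- Single chains only; no side chains, hydrogens, non-standard residues or
  cis-proline omega handling.
- The soft-sphere score is a feasibility filter, not a force field.
- The density projection is random: two runs with different seeds explore
  differently, and a projection can in principle collapse informative
  directions (the standard argument for random projections is average-case,
  not worst-case).
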