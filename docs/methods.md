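# Methods

## Model

The sampler targets a probability density proportional to a non-negative
score Φ over chain conformations, specified as a sparse product of local
factors Φ(x) = Π φ_i(S_i).  The state is *expanded*: joint angles q_1..q_N
together with the frames T_1..T_N they determine (and, for proteins, the
backbone atom positions derived from the frames).  Keeping spatial variables
in the state preserves sparsity — a factor on one atom touches one frame,
not every upstream angle — at the cost of maintaining kinematic consistency,
which the samplers do exactly: frames are recomputed for every accepted
block and the terminal block frame is snapped onto its anchor.

Built-in factors:

* **Ramachandran tables** φ(φ_i, ψ_i) per residue class: piecewise-constant
  probability per square degree on a 10°-binned grid (bilinear interpolation
  available behind a flag).  A zero-probability cell scores 0 and forces
  rejection.
* **B-factor position restraints** φ(p_j) = (c√(2πB_j))⁻¹ exp(−‖p_j − µ_j‖²
  / (2 B_j c²)) with µ_j the reference (native) position, B_j the
  crystallographic B-factor in Å² and c a user confidence scale.  The
  printed normalizer is one-dimensional while the squared distance is
  three-dimensional; as a density this is a convention, and the constant
  cancels in every acceptance ratio, so the sampler is unaffected either
  way.
* **Steric clashes**: binary factors, 0 iff two non-bonded atoms are closer
  than `overlap` × the sum of their van der Waals radii (default overlap
  0.75; radii per element).  Bonded (1-2), angle (1-3) and the tight planar
  peptide 1-4 pairs are excluded, including pairs that span the loop/anchor
  boundary.  Clash factors are evaluated *after* the acceptance draw: a
  binary factor commutes with the Metropolis test, so deferral changes cost
  only (a test runs both orders on one random stream and asserts identical
  trajectories).
* **Side-chain rotamer mixtures**: per residue type and (φ, ψ) bin, a
  Gaussian mixture over the χ vector; sampled ancestrally (component by
  weight, then the Gaussian, wrapped to (−π, π]).

All factor arithmetic is done in log space; hard zeros map to −inf.

## The block move

A block is b consecutive angles with both flanking frames held fixed.  Its
closing conformations form a (b − 6)-dimensional manifold in 3D (b − 3 in
2D).  One move:

1. sample the independent angles y (the first b − 6) from a proposal P;
2. close the dependent 6 (3) angles by IK; on failure the move counts as a
   rejection (this keeps detailed balance — the reverse proposal density at
   the retained state is still well defined);
3. pick one of the s solutions uniformly;
4. accept with α = min(1, Φ_B(x′) Q(x|·) / (Φ_B(x) Q(x′|·))), where
   Q = P(y) / (s √det G) and both the forward and the reverse Q are
   evaluated — the reverse solution count and chart metric are recomputed at
   the current state.

Φ_B multiplies exactly the factors whose domains intersect the block; since
x and x′ differ only inside the block, Φ_B ratios equal full-Φ ratios.

Sweeps update overlapping blocks at one-residue stride (an L-residue loop
has L − 3 blocks); ordering (forward / backward / random) does not affect
the stationary law and is configurable.  Blocks of b ≤ 5 spatial angles are
overdetermined: away from singular conformations the conditional is a Dirac
at the current state, so the sampler returns the identity move directly (a
test asserts the state is bitwise unchanged over 1000 sweeps).  b = 6
restricts the walk to a finite set and is disallowed unless explicitly
enabled.

### Chart geometry

The chart Jacobian stacks the identity over y, the implicit-function-theorem
block ∂z/∂y = −(∂C/∂z)⁻¹ ∂C/∂y, and six rows per intervening frame (origin
velocity and angular velocity, via screw axes and the chain rule).  The
closure residual C is the terminal frame's position error plus the rotation
log of its orientation error; its angle derivatives are the standard
geometric-Jacobian columns [w_j × (p_T − o_j); w_j].  The default weighting
W is 1 on angle rows and frame-origin rows and 0 on frame angular rows —
mixing radians and Ångströms inside one metric has no natural scale, so the
angular rows are dropped by default; W is a fully configurable diagonal.
det G is computed by Cholesky in log space; a non-positive-definite G or a
dependent-subchain Jacobian with reciprocal condition number below 1e−10
(a singular conformation) rejects the step.  Singular conformations are a
measure-zero set, so this does not perturb the stationary law.

### Proposal choices

P(y) enters Q explicitly, so *any* choice leaves the stationary distribution
unchanged; it only affects mixing.  Three modes:

* `prior` (default): each independent φ/ψ from its Ramachandran marginal
  (uniform without a grid);
* `uniform`: uniform on (−π, π];
* `local`: a symmetric Gaussian random walk around the current independent
  angles (default σ = 15°), whose forward/reverse densities cancel in α.

Global (`prior`) proposals mix across basins but close rarely when the
anchors are taut — for a helical block the feasible y-region can be a few
degrees wide — while `local` proposals trade ergodic reach for acceptance.
This trade-off is real: in the loop-completion demonstration the sampler
approaches the native basin but does not fully re-enter it within desk-scale
runs; longer runs or a mixture proposal would be needed for full recovery.

## Inverse kinematics

*Planar 3-angle closure* is solved in closed form (two-circle
intersection): 0, 1 (tangency) or 2 solutions, each closing to 1e−9.

*Spatial 6-angle closure* runs damped Gauss–Newton on the 6-vector residual
from a fixed bank of pseudo-random seed configurations (default 1200;
deterministic, so a problem always returns the same solution set), in two
phases: a short full-bank sweep, then polishing of the seeds that made
progress.  Converged iterates are verified to close within 1e−9 (position
and rotation Frobenius) and deduplicated at 1e−4 rad.  A generic 6R problem
has at most 16 isolated solutions; since every returned root is a verified
closure, the returned set is a subset of the true root set and respects the
bound by construction.  Multistart can in principle miss a root in a narrow
basin; over 1000 randomized self-consistency problems the generating
solution is always recovered at the default bank size, and the sampler
additionally seeds the reverse-move solve with the known current solution.

## Extensions

* **Free endpoints**: interior blocks are ordinary closure blocks (their
  terminal frame is the current Gibbs conditional anchor); the free tail is
  updated by symmetric Gaussian angle perturbation (α = plain Φ ratio).
  A whole-chain Metropolis–Hastings baseline (1° default step) is included
  for scaling comparisons.
* **Planar branched blocks**: trees of revolute joints with multiple
  anchored branches and rings.  For each anchor, the last three joints on
  its path form a dependent subchain closed in topological order; s is the
  product of branch solution counts and G is assembled from the stacked
  multi-constraint implicit Jacobian (block-triangular in topological
  order).  A tree with no branches reduces exactly to the linear planar
  block, which a test asserts numerically.  Extension of branched blocks to
  3D chains is out of scope.

## Diagnostics

Angle series use a circular autocorrelation (correlations of sin(θ −
circular mean)); the recommended skip length is the smallest lag at which
the mean absolute autocorrelation over all series drops below a threshold
(0.2 by default), which is monotone in the threshold by construction.
Ensemble summaries: RMSD in the anchored frame (no superposition — loop
anchors are shared; a Kabsch-superposed variant exists for free chains),
and per-angle circular means and mean absolute circular deviations, either
from the native reference or from the ensemble circular mean.  Outputs are
CSV/JSON tables; plotting is left to the user.

## Synthetic test systems

The fixtures module generates every input deterministically from a seed:

* planar chains (unit links; closed chains initialized on a circular arc
  whose chord is the anchor distance; uniform, von-Mises-angle or
  Gaussian-position priors);
* ideal-geometry mini-proteins (polyalanine helix at (−57°, −47°) or a
  β-basin coil; Engh–Huber-like bonds: N–Cα 1.458 Å, Cα–C 1.525 Å, C–N
  1.329 Å, ω fixed at 180°; synthetic B-factors uniform in [10, 25) Å²),
  written as standard PDB files;
* a two-basin (φ, ψ) probability grid (α and β basins, 10° bins, integral
  1) and a 3-component χ mixture for an arginine-like side chain (σ = 9°);
* random spatial revolute chains, and one fixed 7-joint closed chain whose
  dependent-closure solution count varies from 2 to 8 along its
  one-dimensional manifold — the regime in which the 1/s factor of the
  proposal density is actually exercised (on planar chains the dependent
  closure has exactly two solutions almost everywhere, so 1/s cancels
  identically; a test documents this).

What these fixtures do *not* emulate: real side-chain packing, non-ideal
covalent geometry, solvent, crystallographic symmetry, or sequence-specific
Ramachandran statistics.  Passing tests establish the correctness of the
sampling mathematics and the plumbing, not biophysical realism of the
ensembles.

## Numerical choices

* Dihedral/joint angles in radians internally, degrees at user surfaces;
  angles wrapped to (−π, π].
* Rotation logs via atan2 (no arccos cancellation near the identity);
  near-π handled through the symmetric part of R.
* Closure tolerance 1e−9 (solver verification) / 1e−8 (emitted-state
  invariant); solution deduplication 1e−4 rad; rank decisions at 1e−8 of
  the largest singular value.  All configurable.
* Protein loops loaded from PDB keep native dihedrals but re-close the last
  six angles onto the anchor frame by IK (real covalent geometry deviates
  from the idealized chain, leaving a small terminal gap otherwise);
  altLoc resolves to the highest-occupancy conformer; insertion codes are
  rejected with an explicit error.
* Backbone frame calibration is numerical: relative transforms and atom
  offsets are extracted from an ideal-geometry fragment built at zero
  dihedrals, which guarantees the joint angle equals the IUPAC dihedral
  exactly (round-trip tested to 1e−9).
* The long planar runs use a dedicated plain-float code path; a test
  asserts it agrees with the generic 3D machinery to 1e−9 on both the IK
  solutions and the chart metric.
* Default atom selection for clash checks and B-factor restraints is
  N/Cα/C/O, configurable.

## Validation strategy and problem sizes

The statistical tests compare sampler output against independent oracles:
rejection sampling on the closure manifold with finite-difference chart
volumes (never the analytic metric code), exact marginal densities on
scanned manifolds, and closed-form autocorrelation of AR(1) processes.
Negative controls deliberately omit √det G or 1/s from the proposal density
and must *fail* the distribution tests.  Desk-scale sizes: 1.5×10⁵ sweeps
for the planar 5-angle unbiasedness test (two-sample energy-distance
permutation test at ~850 points per group), ~5×10³ steps for the spatial
7-angle test (~420 points), 2×10⁴ sweeps for the 20-link mixing benchmark,
10³ randomized problems for the IK completeness bound.  These sizes give the
permutation tests comfortable power for the bias magnitudes involved (the
negative controls fail at p ≈ 0.003 while the correct sampler passes at
p ≫ 0.01).

## Known limitations

* The 6R solver is a verified multistart method, not an algebraic
  elimination; completeness is empirical (and bounded above by the true
  root count), not certified per problem.
* Local block moves cross low-score barriers slowly; large-scale loop
  rearrangements need many sweeps (no annealing or restart scheme is
  included).
* Side-chain placement uses generic template geometry (sufficient for the
  sampling mathematics; not a substitute for residue-specific libraries),
  and non-rotameric terminal χ angles are treated with the same Gaussian
  mixture machinery — an acknowledged approximation.
* Branched (multi-loop) blocks are implemented for planar chains only.
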