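# Methods

## The fitting problem

A transition-state force field (TSFF) is an ordinary classical force field
whose bonded parameters have been refit so that the transition-state
geometry of one specific reaction is a *minimum* of the potential energy
surface. That lets standard minimizers and MD engines — all built to seek
minima — hold and sample a saddle-point structure. `tsffit` fits Amber-form
parameters to quantum-chemical reference data for a TS model system by
weighted least squares:

    chi^2 = sum_i  w_i^2 (x_i^0 - x_i)^2

where `x_i^0` is a reference data point (a Cartesian Hessian element or an
internal coordinate of the TS geometry), `x_i` is the same quantity from
the force field, and `w_i` its weight. The potential is the standard Amber
form — harmonic bonds `k_b (r - r_0)^2` and angles `k_th (theta -
theta_0)^2`, Fourier torsions `(V_n / divider)(1 + cos(n phi - gamma))`,
12-6 Lennard-Jones and Coulomb with 1-2/1-3 exclusions and 1-4 scaling
(electrostatics / 1.2, LJ / 2.0, the Amber convention; configurable on the
`Evaluator`). Charges (RESP, supplied with the structure) and
Lennard-Jones parameters are read as input and never refit.

## Data points and weights

**Cartesian-Hessian mode** (the default, appropriate when a single
reference structure is available, as for an enzyme model): one data point
per unique element (i <= j) of the 3N x 3N Cartesian Hessian, weighted by
the topological separation of the element's two atoms:

| pair                      | weight |
|---------------------------|--------|
| same atom (1-1)           | 0.0    |
| 1 or 2 bonds (1-2, 1-3)   | 0.031  |
| 3 bonds (1-4)             | 0.31   |
| further / disconnected    | 0.031  |

Zeroing the same-atom blocks is what makes a saddle fittable as a minimum:
the diagonal curvature along the reaction mode is never compared, while the
off-diagonal couplings that define the stiffness of the environment are.
Elements involving atoms frozen in the reference calculation are also
zero-weighted — constrained atoms carry unphysical second derivatives.

**Eigenmode mode**: the reference Hessian is diagonalized once, H = V E
V^T, and the data points are the reference eigenvalues E_k against the
diagonal of V^T H' V, with the reference eigenvectors V held fixed. The
point for the single negative eigenvalue (the reaction mode) has weight 0,
which inverts the saddle; modes with |E| < 1 kcal/mol/A^2 (translation,
rotation) are also zero-weighted since they carry no parameter
information.

**Geometric points**: bond lengths, angles and torsions of the
FF-*minimized* structure (frozen atoms held at the reference positions)
against the same internals of the reference TS geometry. Torsion residuals
are wrapped into (-180, 180] degrees. Base weights — bonds 100 per A,
angles 2 per degree, torsions 1 per degree, Hessian elements 1 (times the
topological factor) — are package defaults setting the relative scale of
the geometry and curvature blocks; they are deliberate design choices, not
published constants, and are configurable through `ObjectiveWeights`.

**Tethers**: during early rounds, selected parameters (typically
equilibrium angles) receive an extra point pulling them toward an anchor
value with a weight that decreases across macro-cycles (default schedule
10, 3, 0) and ends at zero, so the final answer is tether-free.

A technical point that matters for reproducibility: each objective
evaluation minimizes the geometry starting from an *anchor* that is itself
recomputed from the reference TS coordinates at every stage boundary.
Within a stage the objective is therefore a pure function of the parameter
vector. (A free-running warm start — each evaluation starting from the
previous one's minimum — is faster but path-dependent: one hop into a
neighboring torsional basin during a trial step permanently corrupts every
subsequent Jacobian. We observed exactly this failure mode before fixing
the anchor.)

## Optimizers

**Damped Gauss-Newton.** The Jacobian J_ij = dx_i/dp_j is built by central
differences with per-kind steps (1.0 for force constants, 0.01 A for r_0,
0.5 deg for theta_0, 0.1 for barriers). The step solves (J^T W J + lambda
I) delta = J^T W r with W = diag(w_i^2); lambda starts at zero and is
escalated tenfold until the clamped step lowers chi^2, else the stage
ends. Two implementation details:

* the columns of J are scaled by each parameter's difference step before
  damping, so `lambda I` treats force constants (hundreds of kcal/mol/A^2)
  and bond lengths (about 1.5 A) even-handedly;
* between full central-difference Jacobians, accepted steps update J by
  Broyden rank-1 corrections, with a full refresh every four accepted steps
  or whenever a step is rejected. This cuts the evaluation count several-
  fold at no measurable cost in fit quality.

**Modified simplex.** A bounded Nelder-Mead (alpha=1, gamma=2, rho=0.5,
sigma=0.5) whose reflection centroid is biased toward the best vertex:
`c = (1 - b) * centroid(non-worst) + b * best`, default b = 0.2. With
b = 0 it reproduces a plain Nelder-Mead step for step (asserted against an
independent implementation in the tests). All trial vertices are clamped
to the parameter bounds. The exact form of the bias is our interpretation
of "biasing the reflection point toward the best point(s)"; it is the
part of the optimizer that is a documented design choice rather than a
published formula. The simplex is the default router choice for stages
with at most 40 active parameters; the built-in stage program overrides
this to Gauss-Newton per stage because the Hessian data points are
near-linear in the force constants, which lets Newton reach the recovery
tolerances in a handful of Jacobian builds where the simplex needs
thousands of objective calls.

**Bounds.** Optimized bond and angle force constants are floored at 32.2
kcal/mol/A^2 and optimized dihedral barrier magnitudes at 3.2 kcal/mol;
equilibrium lengths live in [0.5, 3.5] A and angles in (0, 180] deg.
Bounds are enforced by clamping every trial point, never by penalty
terms, so chi^2 keeps its meaning. Parameters not selected for
optimization (and barriers while deliberately held at zero) are exempt.

## The staged program

`staged_fit` runs LOOP rounds of stages; the built-in program is

1. **Round 1 (10% convergence, up to 2 cycles)** — (a) bond and angle
   force constants, with *all dihedral barriers held at zero* to prevent
   the torsions from absorbing bonded curvature; (b) bond lengths, with
   the barriers first restored from the input frcmod values (the input
   file plays the role of the GAFF-derived starting point) clamped to the
   3.2 floor — equilibrium geometry is never refined against freely
   rotating torsions, which we found steers the fit into compensating
   local minima; (c) equilibrium angles under the decreasing tether, the
   anchors pinned to each parameter's initial (reference-derived) value
   for the whole run; (d) the dihedral barriers themselves.
2. **Round 2 (1% convergence, up to 2 cycles)** — a global Gauss-Newton
   refinement over all selected kinds simultaneously, which removes the
   biases the blocked stages leave behind.

Convergence compares chi^2 (without the tether block) between successive
macro-cycles: |chi^2_k - chi^2_{k-1}| <= max(f * chi^2_{k-1}, 1e-8) with
f = 0.10 then 0.01. Charges, LJ parameters and masses are never touched.
Every accepted optimizer step is recorded in a trace (TSV-exportable);
within a stage the accepted chi^2 sequence is non-increasing by
construction. All randomness (none in the default program) would flow from
the loop config's seed; fixed inputs give bit-identical traces.

## The synthetic test system

`make_toy_ts` builds a donor-H-acceptor chain (the middle atom is a
transferred hydrogen with its donor/acceptor angle opened to 150-165 deg)
plus spectator branch hydrogens, with every atom given its own type so
each internal coordinate maps to its own parameter. Oracle parameters are
drawn at GAFF-like magnitudes: bond k in [250, 400] kcal/mol/A^2, angle k
in [40, 80] kcal/mol/rad^2, barriers in [0, 5] kcal/mol (so the 3.2 floor
is occasionally active and the clamps are exercised), r_0 1.10-1.30 A for
X-H and 1.35-1.55 A otherwise. Charges are small random values summing to
zero and fixed thereafter.

The geometry is minimized under the oracle potential; the oracle Hessian's
*softest vibrational eigenvalue* is then replaced by -150 kcal/mol/A^2 (a
typical hydride-transfer curvature scale; configurable) and the reference
Hessian reconstructed in the oracle eigenbasis. The result has exactly one
significant negative eigenvalue and a known reaction vector, while the
generating parameters remain known ground truth.

What the fixture emulates: the geometry + Hessian training data of a
vacuum cluster model with fixed charges. What it does not: the functional-
form mismatch of real QM data (the oracle potential *is* an Amber form, so
recovery here is an upper bound on real-data fidelity), electronic
reorganization, solvent, and the frozen-atom Hessian artifacts of real
constrained optimizations (frozen flags are supported, but the synthetic
reference Hessian is physical everywhere). Passing the recovery tests
therefore demonstrates the machinery — weighting, inversion, bounds,
optimization, convergence — not chemical accuracy for any real enzyme.

One deliberate tension is documented rather than hidden: oracle barriers
are drawn from [0, 5] kcal/mol while optimized barriers are floored at
3.2, so for draws with very soft torsions the *feasible* optimum's chi^2
sits 2-3x above the unconstrained oracle floor (the fit still recovers
bond/angle force constants to ~1% median). The chi^2-floor recovery
property is therefore asserted on cases whose oracle barriers lie above
the floor; the floor behavior itself is asserted separately (a planted
5 kcal/mol/A^2 bond constant comes back at 32.2; a planted 0.5 kcal/mol
barrier comes back at 3.2).

## Problem sizes and numerical choices

The shipped tests fit 12-atom systems (36x36 Hessians, 60-70 parameters)
over ten seeds, which a single core completes in minutes; the evaluator
itself is vectorized (batched finite-difference Hessian, one scatter pass
per term class) and handles a few hundred atoms, the scale of the enzyme
model systems the workflow targets. Other constants: Hessian
finite-difference step 1e-4 A on the analytic gradient; minimizer L-BFGS-B
with RMS-gradient criterion 1e-5 kcal/mol/A over free atoms; "significant"
negative eigenvalue threshold 1 kcal/mol/A^2 separating the reaction mode
from trans/rot noise; Hessians symmetrized as (H + H^T)/2 on parse; the
unit bridge from electronic-structure logs is 627.509474 kcal/mol/Hartree
over (0.529177210903 A/Bohr)^2 ~= 2240.87. Angle gradients clip cos(theta)
into [-1, 1] and guard sin(theta) below 1e-6; torsion geometry is the
atan2 form, safe at the +/-180 deg seam.

## Known limitations

* No periodic boundary conditions, cutoffs, implicit solvent or MD — the
  evaluator targets vacuum cluster models only.
* Impropers are matched only where the parameter file names them (no
  perception) and follow the dihedral functional form.
* One QM-log dialect (geometry table + lower-triangular Cartesian force
  constants in Hartree/Bohr^2) is parsed; other codes are supported via
  the plain-text reference archive.
* Single-structure fitting only: no energy-difference data points across
  multiple reference structures.
* Seminario-style force-constant seeding is an extension point, not
  implemented.
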