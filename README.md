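# tsffit

Automated fitting of **transition-state force fields (TSFFs)** in the Amber
functional form. Given quantum-chemical reference data for a
transition-state model system — the TS geometry and the Cartesian Hessian —
`tsffit` refits the bonded parameters of an Amber-dialect `frcmod` file so
that the transition state becomes a *minimum* of the classical potential,
which ordinary minimizers and MD engines can then hold and sample. The
intended users are computational chemists building reaction-specific force
fields for enzyme active-site models, where QM/MM data exist for exactly
one reference structure.

## The method in brief

Parameters `p_j` are fit by minimizing the penalty function

    chi^2 = sum_i w_i^2 (x_i^0 - x_i)^2

over data points pairing reference values `x_i^0` with force-field values
`x_i`: the unique elements of the 3N x 3N Cartesian Hessian, plus bond
lengths, angles and torsions of the FF-minimized structure against the TS
geometry. Hessian elements are weighted by the bond-count separation of
their two atoms — 0.0 for same-atom (1-1) elements, 0.031 for 1-2/1-3,
0.31 for 1-4, 0.031 beyond — and elements touching atoms frozen in the
reference calculation are zero-weighted. Zeroing the 1-1 blocks (or, in
the alternative eigenmode formulation `E' = V H' V^T`, the weight of the
single negative eigenvalue) is what lets a first-order saddle be
represented as a minimum. Optimization uses a damped Gauss-Newton step
`(J^T W J + lambda I) delta = J^T W r` with a numerically differenced
Jacobian, or a bounded Nelder-Mead simplex whose reflection is biased
toward the best vertex. A staged workflow fits force constants first (with
dihedral barriers held at zero), then bond lengths, then tethered angles,
then dihedral barriers seeded from the input values, cycling to a 10% and
then a 1% convergence criterion; optimized force constants are floored at
32.2 kcal mol^-1 A^-2 (bonds/angles) and 3.2 kcal mol^-1 (dihedral
barriers). See `docs/methods.md` for the full model description.

## Worked example

Generate a synthetic transition-state case (a donor-H-acceptor chain with
known "oracle" parameters and a manufactured reference Hessian carrying
exactly one negative eigenvalue), then fit the perturbed starting
parameters back:

```bash
$ tsffit synth --seed 5 --size 8 --out-dir case
structure: case/structure.pdb
charges: case/charges.lib
frozen: case/fixedatoms.txt
frcmod: case/initial.frcmod
oracle: case/oracle.frcmod
reference: case/reference.qref
loop: case/loop.in

$ tsffit evaluate case/initial.frcmod case/structure.pdb case/charges.lib case/reference.qref
chi^2 = 3129.41 over 318 data points

$ tsffit fit case/loop.in --out-dir fitout
final chi^2: 173.22
fitted parameters: fitout/fitted.frcmod
trace: fitout/trace.tsv
```

The first chi^2 (3129.4) is the penalty of the 20%-perturbed starting
parameters against the reference Hessian and TS internals; the staged fit
reduces it to 173.2, and `fitout/fitted.frcmod` holds the refit force
constants, equilibrium values and barriers (charges and Lennard-Jones
parameters pass through untouched). `fitout/trace.tsv` records every
accepted optimizer step; `fitout/residuals.tsv` lists each data point's
reference value, fitted value and weighted residual for reference-vs-TSFF
comparison plots. Minimizing the fitted TSFF from the TS geometry stays on
the TS (an RMSD of a few thousandths of an Angstrom here) with no negative
curvature left beyond translation/rotation:

```bash
$ tsffit minimize fitout/fitted.frcmod case/structure.pdb case/charges.lib
converged: True  E = -0.4852 kcal/mol  rms grad = 2.04e-07  iterations = 43
RMSD from start: 0.0037 A
```

The same operations are available as a library (`tsffit.make_toy_ts`,
`tsffit.staged_fit`, `tsffit.CartesianObjective`, ...), which is how the
test suite drives them.

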