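"""Parameter optimization: handle mapping, numerical Jacobian, damped
Gauss-Newton steps, the bias-modified simplex, and the staged workflow.

Parameters live in the frcmod file; a :class:`ParameterHandle` maps one
numeric field (a bond force constant, an equilibrium length, ...) to a slot
of the optimization vector, with bounds enforced by clamping every trial
point. Force constants are floored at 32.2 kcal mol^-1 A^-2 for bonds and
angles and 3.2 kcal mol^-1 for dihedral barriers when those kinds are being
optimized, which keeps the fitted surface from going soft and distorting
optimized geometries.

The staged workflow fits force constants first with dihedral barriers held
at zero, then refines bond lengths, then angles under a decreasing tether,
then seeds dihedral barriers from the input (GAFF-derived) values and fits
them; the stage list is cycled until the penalty function changes by less
than the round's convergence fraction (10%, then 1%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .frcmod import FrcmodParameterSet
from .loopcfg import LoopConfig, RoundSpec, StageSpec, default_stage_program
from .objective import (
    CartesianObjective,
    EigenmodeObjective,
    ObjectiveWeights,
    _ObjectiveBase,
)
from .qmref import ReferenceData
from .structures import MolecularSystem

__all__ = [
    "BOND_ANGLE_K_FLOOR",
    "DIHEDRAL_V_FLOOR",
    "ParameterHandle",
    "SelectionError",
    "select_parameters",
    "numerical_jacobian",
    "newton_step",
    "modified_simplex",
    "FitTrace",
    "TraceRecord",
    "staged_fit",
    "FitProblem",
]

BOND_ANGLE_K_FLOOR = 32.2   # kcal/mol/A^2 (bonds) and kcal/mol/rad^2 (angles)
DIHEDRAL_V_FLOOR = 3.2      # kcal/mol

_KIND_SPEC = {
    # kind: (section, field, lower, upper, fd step)
    "bond_k": ("BOND", "k", BOND_ANGLE_K_FLOOR, 5000.0, 1.0),
    "bond_r0": ("BOND", "r0", 0.5, 3.5, 0.01),
    "angle_k": ("ANGLE", "k", BOND_ANGLE_K_FLOOR, 2000.0, 1.0),
    "angle_theta0": ("ANGLE", "theta0", 1e-3, 180.0, 0.5),
    "dihedral_V": ("DIHE", "barrier", DIHEDRAL_V_FLOOR, 200.0, 0.1),
}


class SelectionError(ValueError):
    pass


@dataclass
class ParameterHandle:
    kind: str
    section: str
    key: tuple
    term_index: int
    field_name: str
    lower: float
    upper: float
    step: float
    tether_anchor: float | None = None
    tether_weight: float = 0.0

    @property
    def identifier(self) -> tuple:
        return (self.section, "-".join(self.key), self.term_index, self.field_name)

    def get(self, params: FrcmodParameterSet) -> float:
        if self.section == "BOND":
            return getattr(params.bond_terms[self.key], self.field_name)
        if self.section == "ANGLE":
            return getattr(params.angle_terms[self.key], self.field_name)
        return getattr(
            params.dihedral_terms[self.key][self.term_index], self.field_name
        )

    def set(self, params: FrcmodParameterSet, value: float) -> None:
        value = float(np.clip(value, self.lower, self.upper))
        if self.section == "BOND":
            setattr(params.bond_terms[self.key], self.field_name, value)
        elif self.section == "ANGLE":
            setattr(params.angle_terms[self.key], self.field_name, value)
        else:
            setattr(
                params.dihedral_terms[self.key][self.term_index],
                self.field_name,
                value,
            )

    @property
    def value(self) -> float:
        # convenience mirror used by tether_points; kept in sync by FitProblem
        return getattr(self, "_value", float("nan"))

    @value.setter
    def value(self, v: float) -> None:
        self._value = v


def select_parameters(params: FrcmodParameterSet, kinds) -> list[ParameterHandle]:
    """One handle per matching frcmod field, with kind-specific bounds.

    An empty result raises :class:`SelectionError` (it almost always means a
    typo'd kind or an empty parameter file).
    """
    kinds = list(kinds)
    if not kinds:
        raise SelectionError("empty parameter-kind selection")
    bad = [k for k in kinds if k not in _KIND_SPEC]
    if bad:
        raise SelectionError(f"unknown parameter kinds {bad}")
    handles: list[ParameterHandle] = []
    for kind in kinds:
        section, fname, lo, hi, step = _KIND_SPEC[kind]
        if section == "BOND":
            keys = [(k, 0) for k in params.bond_terms]
        elif section == "ANGLE":
            keys = [(k, 0) for k in params.angle_terms]
        else:
            keys = [
                (k, t)
                for k, terms in params.dihedral_terms.items()
                for t in range(len(terms))
            ]
        for key, t in keys:
            h = ParameterHandle(
                kind=kind, section=section, key=key, term_index=t,
                field_name=fname, lower=lo, upper=hi, step=step,
            )
            h.value = h.get(params)
            handles.append(h)
    if not handles:
        raise SelectionError(f"no parameters matched kinds {kinds}")
    return handles


def numerical_jacobian(handles, calc_fn, x0=None) -> np.ndarray:
    """J_ij = d x_i / d p_j by central difference with each handle's step.

    ``calc_fn`` maps a parameter vector to the vector of calculated data
    points; the evaluation count is exactly 2 x len(handles).
    """
    if x0 is None:
        x0 = np.array([h.value for h in handles], dtype=float)
    x0 = np.asarray(x0, dtype=float)
    cols = []
    for j, h in enumerate(handles):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h.step
        xm[j] -= h.step
        try:
            fp = np.asarray(calc_fn(xp), dtype=float)
            fm = np.asarray(calc_fn(xm), dtype=float)
        except Exception as exc:
            raise RuntimeError(
                f"objective failed while differencing handle {h.identifier}"
            ) from exc
        cols.append((fp - fm) / (2.0 * h.step))
    return np.column_stack(cols)


def newton_step(J, residuals, weights, damping: float = 0.0) -> np.ndarray:
    """Solve (J^T W J + lambda I) delta = J^T W r with W = diag(w_i^2).

    A singular system at lambda = 0 is retried with increasing damping
    rather than raised.
    """
    J = np.asarray(J, dtype=float)
    r = np.asarray(residuals, dtype=float)
    w2 = np.asarray(weights, dtype=float) ** 2
    a = J.T @ (w2[:, None] * J)
    b = J.T @ (w2 * r)
    lam = damping
    eye = np.eye(a.shape[0])
    for _ in range(12):
        try:
            delta = np.linalg.solve(a + lam * eye, b)
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None and np.all(np.isfinite(delta)):
            return delta
        lam = max(lam * 10.0, 1e-8)
    return np.zeros(a.shape[0])


def modified_simplex(
    fun,
    x0,
    bounds,
    max_iter: int = 200,
    bias: float = 0.2,
    spread: float = 0.05,
    min_spread=None,
    callback=None,
    ftol: float = 1e-12,
):
    """Bounded Nelder-Mead with the reflection centroid biased toward the
    best vertex: c = (1 - b) * centroid(non-worst) + b * best. With b = 0
    this is the standard method (alpha=1, gamma=2, rho=0.5, sigma=0.5); the
    bias pulls reflected trial points toward the best region of parameter
    space, which speeds convergence on the modest parameter counts (<~40)
    this optimizer is routed to. All trial points are clamped to bounds.
    """
    x0 = np.asarray(x0, dtype=float)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    n = x0.size

    def clamp(x):
        return np.clip(x, lo, hi)

    if min_spread is None:
        min_spread = np.full(n, 1e-4)
    else:
        min_spread = np.asarray(min_spread, dtype=float)

    verts = [clamp(x0)]
    for j in range(n):
        v = x0.copy()
        dx = max(abs(x0[j]) * spread, min_spread[j])
        v[j] = x0[j] + dx if x0[j] + dx <= hi[j] else x0[j] - dx
        verts.append(clamp(v))
    verts = np.array(verts)
    fvals = np.array([fun(v) for v in verts])

    n_eval = n + 1
    for it in range(max_iter):
        order = np.argsort(fvals, kind="stable")
        verts, fvals = verts[order], fvals[order]
        best, worst = fvals[0], fvals[-1]
        if callback is not None:
            callback(it, best, verts[0])
        if abs(worst - best) <= ftol * max(1.0, abs(best)):
            break
        c0 = verts[:-1].mean(axis=0)
        c = (1.0 - bias) * c0 + bias * verts[0]
        xr = clamp(c + (c - verts[-1]))
        fr = fun(xr)
        n_eval += 1
        if fr < fvals[0]:
            xe = clamp(c + 2.0 * (c - verts[-1]))
            fe = fun(xe)
            n_eval += 1
            if fe < fr:
                verts[-1], fvals[-1] = xe, fe
            else:
                verts[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            verts[-1], fvals[-1] = xr, fr
        else:
            if fr < fvals[-1]:
                xc = clamp(c + 0.5 * (xr - c))
            else:
                xc = clamp(c + 0.5 * (verts[-1] - c))
            fc = fun(xc)
            n_eval += 1
            if fc < min(fr, fvals[-1]):
                verts[-1], fvals[-1] = xc, fc
            else:
                # shrink toward the best vertex
                for k in range(1, n + 1):
                    verts[k] = clamp(verts[0] + 0.5 * (verts[k] - verts[0]))
                    fvals[k] = fun(verts[k])
                n_eval += n
    order = np.argsort(fvals, kind="stable")
    return verts[order][0], float(fvals[order][0]), n_eval


@dataclass
class TraceRecord:
    stage: str
    iteration: int
    chi2: float
    parameters: np.ndarray
    step_kind: str
    accepted: bool


@dataclass
class FitTrace:
    records: list[TraceRecord] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.records.append(TraceRecord(**kw))

    def to_tsv(self) -> str:
        lines = ["stage\titeration\tchi2\tstep_kind\taccepted\tparameters"]
        for r in self.records:
            pvec = ",".join(f"{v:.10g}" for v in r.parameters)
            lines.append(
                f"{r.stage}\t{r.iteration}\t{r.chi2:.10e}\t{r.step_kind}"
                f"\t{int(r.accepted)}\t{pvec}"
            )
        return "\n".join(lines) + "\n"

    def accepted_chi2(self, stage: str) -> list[float]:
        return [r.chi2 for r in self.records if r.stage == stage and r.accepted]


class FitProblem:
    """Binds an objective, a working parameter set and a handle list into
    vector callables (calculated values, chi^2) with tether points appended."""

    def __init__(
        self,
        objective: _ObjectiveBase,
        params: FrcmodParameterSet,
        handles: list[ParameterHandle],
        tether_weight: float = 0.0,
    ):
        self.objective = objective
        self.params = params
        self.handles = handles
        for h in handles:
            h.value = h.get(params)
            if h.tether_anchor is None:
                h.tether_anchor = h.value
            h.tether_weight = tether_weight
        self.anchors = np.array([h.tether_anchor for h in handles])
        self.tether_w = np.full(len(handles), tether_weight)

    def vector(self) -> np.ndarray:
        return np.array([h.get(self.params) for h in self.handles])

    def bounds(self):
        return [(h.lower, h.upper) for h in self.handles]

    def steps(self) -> np.ndarray:
        return np.array([h.step for h in self.handles])

    def apply(self, x) -> np.ndarray:
        for h, v in zip(self.handles, x):
            h.set(self.params, v)
            h.value = h.get(self.params)
        return self.vector()

    def calculated(self, x) -> np.ndarray:
        xc = self.apply(x)
        base = self.objective.calculated(self.params)
        return np.concatenate([base, xc])

    @property
    def ref_values(self) -> np.ndarray:
        return np.concatenate([self.objective.ref_values, self.anchors])

    @property
    def weights(self) -> np.ndarray:
        return np.concatenate([self.objective.point_weights, self.tether_w])

    def chi2(self, x) -> float:
        r = self.ref_values - self.calculated(x)
        return float(np.sum((self.weights * r) ** 2))

    def chi2_base(self) -> float:
        """Penalty function without the tether block, at current parameters."""
        return self.objective.chi2(self.params)


def _run_stage(problem: FitProblem, spec: StageSpec, stage_name: str, trace: FitTrace):
    x0 = problem.vector()
    n = len(problem.handles)
    optimizer = spec.optimizer
    if optimizer == "auto":
        optimizer = "simplex" if n <= 40 else "newton"

    # fix the warm-start anchor at the stage's starting parameters so the
    # objective is a pure function of the parameter vector within the stage
    problem.objective.rebase(problem.params)
    f0 = problem.chi2(x0)
    trace.append(
        stage=stage_name, iteration=0, chi2=f0, parameters=x0.copy(),
        step_kind="start", accepted=True,
    )

    if optimizer == "simplex":
        best_seen = {"f": f0}

        def cb(it, fbest, xbest):
            fbest = min(fbest, best_seen["f"])
            best_seen["f"] = fbest
            trace.append(
                stage=stage_name, iteration=it + 1, chi2=fbest,
                parameters=np.asarray(xbest).copy(), step_kind="simplex",
                accepted=True,
            )

        max_iter = spec.max_iter if spec.max_iter is not None else 200
        xb, fb, _ = modified_simplex(
            problem.chi2, x0, problem.bounds(), max_iter=max_iter,
            min_spread=problem.steps(), callback=cb,
        )
        if fb <= f0:
            problem.apply(xb)
        else:  # never accept a worse vector than the start
            problem.apply(x0)
        return

    # damped Gauss-Newton, preconditioned by each handle's natural scale
    # (its finite-difference step) so the lambda*I damping treats force
    # constants, lengths and angles even-handedly. Between full central-
    # difference Jacobians, accepted steps refresh J by Broyden rank-1
    # updates, which is what keeps the evaluation count affordable.
    max_iter = spec.max_iter if spec.max_iter is not None else 8
    scale = problem.steps()
    lo = np.array([h.lower for h in problem.handles])
    hi = np.array([h.upper for h in problem.handles])
    x = x0.copy()
    fx = f0
    w2 = problem.weights**2
    calc_x = problem.calculated(x)
    J = None
    fresh = False
    since_full = 0
    prev_fx = None
    for it in range(1, max_iter + 1):
        if J is None or since_full >= 4:
            J = numerical_jacobian(problem.handles, problem.calculated, x)
            fresh = True
            since_full = 0
        r = problem.ref_values - calc_x
        J_scaled = J * scale[None, :]
        lam = 0.0
        accepted = False
        for _trial in range(9):
            delta = scale * newton_step(J_scaled, r, problem.weights, damping=lam)
            xt = np.clip(x + delta, lo, hi)
            calc_t = problem.calculated(xt)
            ft = float(np.sum(w2 * (problem.ref_values - calc_t) ** 2))
            if ft < fx:
                step_vec = xt - x
                denom = float(step_vec @ step_vec)
                if denom > 0:
                    J = J + np.outer(
                        (calc_t - calc_x) - J @ step_vec, step_vec
                    ) / denom
                x, fx, calc_x = xt, ft, calc_t
                accepted = True
                fresh = False
                since_full += 1
                trace.append(
                    stage=stage_name, iteration=it, chi2=fx, parameters=x.copy(),
                    step_kind=f"newton(lam={lam:g})", accepted=True,
                )
                break
            lam = 10.0 * max(lam, 1e-4)
        if not accepted:
            if not fresh:
                # the Broyden approximation may be stale: retry once with a
                # freshly differenced Jacobian before giving up
                J = None
                continue
            trace.append(
                stage=stage_name, iteration=it, chi2=fx, parameters=x.copy(),
                step_kind="newton-rejected", accepted=False,
            )
            break
        if prev_fx is not None and abs(prev_fx - fx) <= 1e-4 * max(1e-12, fx):
            break
        prev_fx = fx
    problem.apply(x)


def _make_objective(mode, ref, system, params, weights):
    if mode == "eigenmode":
        return EigenmodeObjective(ref, system, params, weights)
    return CartesianObjective(ref, system, params, weights)


def staged_fit(
    config: LoopConfig | None,
    ref: ReferenceData,
    system: MolecularSystem,
    params: FrcmodParameterSet,
    *,
    weights: ObjectiveWeights | None = None,
    trace_path=None,
):
    """Run the staged parameterization workflow.

    Charges and Lennard-Jones parameters are never touched: only the bonded
    kinds named by each stage enter the optimization vector. Returns
    ``(fitted FrcmodParameterSet, FitTrace)``. If a stage raises, the trace
    collected so far is written to ``trace_path`` (when given) before the
    exception propagates.
    """
    if config is None:
        config = LoopConfig(rounds=default_stage_program())
    working = params.copy()
    trace = FitTrace()
    dihedral_seeds = {
        key: [t.barrier for t in terms]
        for key, terms in params.dihedral_terms.items()
    }
    zero_done = False
    seed_done = False
    # tether anchors are the values at a parameter's first selection (the
    # reference-derived initial values), fixed across cycles so the tether
    # pins rather than follows the drift
    anchors: dict[tuple, float] = {}

    try:
        objective = _make_objective(config.mode, ref, system, working, weights)
        for rnd_idx, rnd in enumerate(config.rounds, start=1):
            prev = objective.chi2(working)
            for cycle in range(1, rnd.max_cycles + 1):
                for st_idx, spec in enumerate(rnd.stages, start=1):
                    stage_name = f"r{rnd_idx}c{cycle}s{st_idx}:" + "+".join(spec.kinds)
                    if spec.zero_dihedrals and not zero_done:
                        for terms in working.dihedral_terms.values():
                            for t in terms:
                                t.barrier = 0.0
                        zero_done = True
                    if spec.seed_dihedrals and not seed_done:
                        for key, terms in working.dihedral_terms.items():
                            for t, seed_v in zip(terms, dihedral_seeds[key]):
                                t.barrier = max(abs(seed_v), DIHEDRAL_V_FLOOR)
                        seed_done = True
                    handles = select_parameters(working, spec.kinds)
                    for h in handles:
                        h.tether_anchor = anchors.setdefault(
                            h.identifier, h.get(working)
                        )
                    t_sched = spec.tether
                    t_w = (
                        t_sched[min(cycle - 1, len(t_sched) - 1)] if t_sched else 0.0
                    )
                    problem = FitProblem(objective, working, handles, tether_weight=t_w)
                    _run_stage(problem, spec, stage_name, trace)
                chi2 = objective.chi2(working)
                # relative criterion, with an absolute floor for objectives
                # already at numerical zero
                if abs(chi2 - prev) <= max(rnd.convergence * prev, 1e-8):
                    prev = chi2
                    break
                prev = chi2
            else:
                warnings.warn(
                    f"round {rnd_idx} hit max_cycles={rnd.max_cycles} without "
                    f"meeting the {rnd.convergence:.0%} criterion",
                    stacklevel=2,
                )
    except Exception:
        if trace_path is not None:
            with open(trace_path, "w") as fh:
                fh.write(trace.to_tsv())
        raise
    if trace_path is not None:
        with open(trace_path, "w") as fh:
            fh.write(trace.to_tsv())
    return working, trace
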