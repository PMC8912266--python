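"""Optimizers and parameter handles: selection floors, Jacobian accuracy,
Gauss-Newton exactness, modified simplex behavior."""

import numpy as np
import pytest

from tsffit.fitting import (
    BOND_ANGLE_K_FLOOR,
    DIHEDRAL_V_FLOOR,
    SelectionError,
    modified_simplex,
    newton_step,
    numerical_jacobian,
    select_parameters,
)

from conftest import random_params


# ---------------------------------------------------------------- selection

def test_select_bond_k_floors(small_case):
    handles = select_parameters(small_case.oracle_params, ["bond_k"])
    assert len(handles) == len(small_case.oracle_params.bond_terms)
    assert all(h.lower == BOND_ANGLE_K_FLOOR for h in handles)
    assert all(h.kind == "bond_k" for h in handles)


def test_select_dihedral_floors(small_case):
    handles = select_parameters(small_case.oracle_params, ["dihedral_V"])
    assert handles and all(h.lower == DIHEDRAL_V_FLOOR for h in handles)


def test_select_r0_theta0_ranges(small_case):
    for kind, lo, hi in (("bond_r0", 0.5, 3.5), ("angle_theta0", 1e-3, 180.0)):
        handles = select_parameters(small_case.oracle_params, [kind])
        assert all((h.lower, h.upper) == (lo, hi) for h in handles)


def test_empty_selection_is_error(small_case):
    with pytest.raises(SelectionError):
        select_parameters(small_case.oracle_params, [])
    with pytest.raises(SelectionError):
        select_parameters(small_case.oracle_params, ["bogus_kind"])


def test_handle_set_clamps_to_bounds(small_case):
    params = small_case.oracle_params.copy()
    h = select_parameters(params, ["bond_k"])[0]
    h.set(params, 1.0)  # below the floor
    assert h.get(params) == BOND_ANGLE_K_FLOOR


# ---------------------------------------------------------------- Jacobian

class _Probe:
    """Linear/quadratic probe handles for differencing tests."""

    def __init__(self, step=0.05):
        self.kind = "probe"
        self.section = "BOND"
        self.key = ("p",)
        self.term_index = 0
        self.field_name = "k"
        self.lower, self.upper = -1e9, 1e9
        self.step = step
        self.value = 1.0
        self.identifier = ("probe",)


def test_jacobian_linear_probe_exact():
    h = _Probe()
    calls = []

    def fn(x):
        calls.append(x.copy())
        return np.array([2.0 * x[0], 7.0])

    J = numerical_jacobian([h], fn, np.array([1.0]))
    assert J[0, 0] == pytest.approx(2.0, abs=1e-8)
    assert J[1, 0] == pytest.approx(0.0, abs=1e-12)  # independent point: zero column
    assert len(calls) == 2  # exactly 2 evaluations per parameter


def test_jacobian_second_order_convergence():
    # quadratic probe: central-difference error on f' is O(step^2) -> exact
    # for quadratics; use a cubic to see the step^2 scaling
    errs = []
    for step in (0.2, 0.1):
        h = _Probe(step=step)
        J = numerical_jacobian([h], lambda x: np.array([x[0] ** 3]), np.array([1.0]))
        errs.append(abs(J[0, 0] - 3.0))
    assert errs[1] == pytest.approx(errs[0] / 4.0, rel=0.05)


def test_jacobian_failure_names_handle():
    h = _Probe()

    def bad(x):
        raise FloatingPointError("boom")

    with pytest.raises(RuntimeError, match="probe"):
        numerical_jacobian([h], bad, np.array([1.0]))


# ------------------------------------------------------------- Newton step

def test_newton_one_step_on_linear_model():
    """Gauss-Newton is exact for linear residuals: one step to the optimum."""
    rng = np.random.default_rng(0)
    A = rng.normal(size=(12, 3))
    x_true = np.array([1.5, -2.0, 0.7])
    x0 = np.zeros(3)
    w = rng.uniform(0.5, 2.0, size=12)
    ref = A @ x_true
    r = ref - A @ x0
    delta = newton_step(A, r, w, damping=0.0)
    assert np.allclose(x0 + delta, x_true, atol=1e-8)


def test_newton_zero_residual_zero_step():
    A = np.eye(4)
    delta = newton_step(A, np.zeros(4), np.ones(4))
    assert np.allclose(delta, 0.0)


def test_newton_matches_normal_equations_oracle():
    rng = np.random.default_rng(1)
    for _ in range(5):
        J = rng.normal(size=(20, 6))
        r = rng.normal(size=20)
        w = rng.uniform(0.1, 3.0, size=20)
        lam = 0.3
        delta = newton_step(J, r, w, damping=lam)
        W = np.diag(w**2)
        expected = np.linalg.solve(J.T @ W @ J + lam * np.eye(6), J.T @ W @ r)
        assert np.allclose(delta, expected, atol=1e-8)


def test_newton_singular_system_not_raised():
    J = np.zeros((5, 3))  # J^T W J singular at lambda = 0
    delta = newton_step(J, np.ones(5), np.ones(5), damping=0.0)
    assert np.all(np.isfinite(delta))


# --------------------------------------------------------- modified simplex

def _quad(center, scales):
    center = np.asarray(center)
    scales = np.asarray(scales)

    def f(x):
        return float(np.sum(scales * (np.asarray(x) - center) ** 2))

    return f


def test_simplex_preserves_optimal_start_vertex():
    f = _quad([0.5, -0.2], [1.0, 3.0])
    x, fx, _ = modified_simplex(
        f, np.array([0.5, -0.2]), [(-5, 5), (-5, 5)], max_iter=50
    )
    assert fx <= f(np.array([0.5, -0.2])) + 1e-15
    assert np.allclose(x, [0.5, -0.2], atol=1e-3)


def test_simplex_two_parameter_bowl():
    f = _quad([1.2, -0.7], [2.0, 0.5])
    x, fx, _ = modified_simplex(
        f, np.array([0.0, 0.0]), [(-5, 5), (-5, 5)], max_iter=200
    )
    assert fx < 1e-6


def test_simplex_respects_bounds():
    f = _quad([10.0, 10.0], [1.0, 1.0])  # optimum outside the box
    x, fx, _ = modified_simplex(
        f, np.array([0.0, 0.0]), [(-1, 2), (-1, 2)], max_iter=300
    )
    assert np.all(x <= 2.0 + 1e-12) and np.all(x >= -1.0 - 1e-12)
    assert np.allclose(x, [2.0, 2.0], atol=1e-3)


def _reference_nelder_mead(f, x0, spread, min_spread, max_iter):
    """Independent unbiased Nelder-Mead (alpha=1, gamma=2, rho=0.5, sigma=0.5)
    mirroring the tie-break and vertex-initialization conventions."""
    n = len(x0)
    verts = [np.asarray(x0, float)]
    for j in range(n):
        v = np.array(x0, float)
        v[j] += max(abs(x0[j]) * spread, min_spread)
        verts.append(v)
    verts = np.array(verts)
    fvals = np.array([f(v) for v in verts])
    history = []
    for _ in range(max_iter):
        order = np.argsort(fvals, kind="stable")
        verts, fvals = verts[order], fvals[order]
        history.append(verts[0].copy())
        c = verts[:-1].mean(axis=0)
        xr = c + (c - verts[-1])
        fr = f(xr)
        if fr < fvals[0]:
            xe = c + 2 * (c - verts[-1])
            fe = f(xe)
            if fe < fr:
                verts[-1], fvals[-1] = xe, fe
            else:
                verts[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            verts[-1], fvals[-1] = xr, fr
        else:
            xc = c + 0.5 * ((xr if fr < fvals[-1] else verts[-1]) - c)
            fc = f(xc)
            if fc < min(fr, fvals[-1]):
                verts[-1], fvals[-1] = xc, fc
            else:
                for k in range(1, n + 1):
                    verts[k] = verts[0] + 0.5 * (verts[k] - verts[0])
                    fvals[k] = f(verts[k])
    return np.array(history)


def test_zero_bias_reproduces_unbiased_nelder_mead():
    """With bias = 0 the modified simplex must follow a reference unbiased
    implementation step for step on an unbounded quadratic."""
    f = _quad([0.8, -1.1, 0.3], [1.0, 2.0, 0.5])
    x0 = np.array([2.0, 2.0, 2.0])
    steps = []
    modified_simplex(
        f, x0, [(-1e9, 1e9)] * 3, max_iter=40, bias=0.0,
        min_spread=np.full(3, 1e-4), ftol=0.0,
        callback=lambda it, fb, xb: steps.append(np.array(xb)),
    )
    ref_hist = _reference_nelder_mead(f, x0, 0.05, 1e-4, 40)
    assert np.allclose(np.array(steps), ref_hist, atol=1e-12)


def test_bias_pulls_reflection_toward_best():
    """A biased reflection must differ from the unbiased one when the best
    vertex is off-centroid (sanity check that the bias parameter acts)."""
    f = _quad([0.0, 0.0], [1.0, 1.0])
    x0 = np.array([1.0, 1.0])
    trajs = {}
    for bias in (0.0, 0.4):
        steps = []
        modified_simplex(
            f, x0, [(-10, 10)] * 2, max_iter=15, bias=bias, ftol=0.0,
            callback=lambda it, fb, xb: steps.append(fb),
        )
        trajs[bias] = steps
    assert trajs[0.0] != trajs[0.4]
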