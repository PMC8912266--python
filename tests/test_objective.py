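"""Penalty function: chi^2 arithmetic, Cartesian-Hessian and eigenmode
data-point assembly, frozen-atom zeroing, tethers."""

import numpy as np
import pytest

from tsffit.objective import (
    CartesianObjective,
    DataPoint,
    ObjectiveWeights,
    assemble_cartesian_points,
    chi_squared,
    eigenmode_points,
    tether_points,
)
from tsffit.fitting import select_parameters
from tsffit.qmref import ReferenceData
from tsffit.synth import make_toy_ts


def test_chi_squared_zero_residual():
    pts = [DataPoint(("x", i), 1.2 * i, 1.2 * i, 3.0) for i in range(5)]
    assert chi_squared(pts) == 0.0


def test_chi_squared_direct_arithmetic():
    # w^2 (x0 - x)^2 = 4 * 1 = 4
    assert chi_squared([DataPoint(("p",), 1.5, 0.5, 2.0)]) == pytest.approx(4.0)


def test_chi_squared_matches_summation_oracle():
    rng = np.random.default_rng(0)
    ref, calc, w = rng.normal(size=1000), rng.normal(size=1000), rng.uniform(0, 5, 1000)
    pts = [DataPoint(("r", i), ref[i], calc[i], w[i]) for i in range(1000)]
    expected = 0.0
    for i in range(1000):  # independent plain-python summation
        expected += (w[i] * (ref[i] - calc[i])) ** 2
    assert chi_squared(pts) == pytest.approx(expected, rel=1e-10)


def test_negative_weight_rejected():
    with pytest.raises(ValueError, match="weight"):
        DataPoint(("p",), 1.0, 1.0, -0.1)


def test_cartesian_point_count_and_diagonal_zero(small_case):
    """3N(3N+1)/2 unique Hessian points plus the geometric internals; all
    same-atom (1-1) Hessian elements carry weight 0."""
    pts = assemble_cartesian_points(
        small_case.reference, small_case.system, small_case.oracle_params
    )
    n3 = 3 * small_case.system.n_atoms
    hess_pts = [p for p in pts if p.label[0] == "hessian"]
    assert len(hess_pts) == n3 * (n3 + 1) // 2
    from tsffit.topology import enumerate_internals

    table = enumerate_internals(small_case.system)
    geo = len(table.bonds) + len(table.angles) + len(table.torsions)
    assert len(pts) == len(hess_pts) + geo
    for p in hess_pts:
        if p.label[1] // 3 == p.label[2] // 3:  # same atom
            assert p.weight == 0.0


def test_atom_count_mismatch_raises(small_case, toy_case):
    with pytest.raises(ValueError, match="atoms"):
        assemble_cartesian_points(
            toy_case.reference, small_case.system, small_case.oracle_params
        )


def test_all_atoms_frozen_zeroes_hessian_block(small_case):
    system = small_case.system
    system_frozen = type(system)(
        atoms=system.atoms,
        coordinates=system.coordinates,
        bonds=system.bonds,
        frozen=np.ones(system.n_atoms, dtype=bool),
    )
    pts = assemble_cartesian_points(
        small_case.reference, system_frozen, small_case.oracle_params
    )
    hess = [p for p in pts if p.label[0] == "hessian"]
    assert all(p.weight == 0.0 for p in hess)
    assert chi_squared(hess) == 0.0


def test_eigenmode_identity_case(toy_case):
    """H' = H_ref reproduces every eigenvalue: zero chi^2."""
    ref = toy_case.reference
    pts = eigenmode_points(ref, ref.hessian)
    assert chi_squared(pts) == pytest.approx(0.0, abs=1e-10)
    for p in pts:
        assert p.calculated == pytest.approx(p.reference, abs=1e-6)


def test_negative_mode_point_has_zero_weight(toy_case):
    ref = toy_case.reference
    rng = np.random.default_rng(2)
    a = rng.normal(size=ref.hessian.shape)
    pts = eigenmode_points(ref, a + a.T)
    neg = [p for p in pts if p.label == ("eigenvalue", ref.negative_mode_index)]
    assert len(neg) == 1 and neg[0].weight == 0.0
    # and it contributes nothing regardless of H'
    assert neg[0].weight ** 2 * (neg[0].reference - neg[0].calculated) ** 2 == 0.0


def test_eigenmode_diagonal_matches_matrix_product_oracle():
    rng = np.random.default_rng(3)
    coords = rng.normal(size=(2, 3)) * 2
    base = rng.normal(size=(6, 6)) * 50
    h_ref = base + base.T
    ref = ReferenceData(elements=["C", "O"], coordinates=coords, hessian=h_ref)
    hp = rng.normal(size=(6, 6))
    hp = hp + hp.T
    pts = eigenmode_points(ref, hp)
    v = ref.eigenvectors
    expected = np.diag(v.T @ hp @ v)  # independent dense product
    got = np.array([p.calculated for p in pts])
    assert np.allclose(got, expected, atol=1e-10)


def test_trans_rot_modes_zero_weight(toy_case):
    ref = toy_case.reference
    pts = eigenmode_points(ref, ref.hessian)
    for k in ref.trans_rot_indices:
        assert pts[k].weight == 0.0


def test_tether_points_arithmetic(small_case):
    handles = select_parameters(small_case.oracle_params, ["angle_theta0"])
    h = handles[0]
    h.tether_anchor = 120.0
    h.value = 118.0
    pts = tether_points([h], tether_weights=[10.0])
    # 10^2 * (120 - 118)^2 = 400
    assert chi_squared(pts) == pytest.approx(400.0)
    assert chi_squared(tether_points([h], tether_weights=[0.0])) == 0.0


def test_tether_schedule_strictly_decreases_block(small_case):
    handles = select_parameters(small_case.oracle_params, ["angle_theta0"])
    for h in handles:
        h.tether_anchor = h.value + 2.0  # fixed parameters, fixed anchors
    blocks = [
        chi_squared(tether_points(handles, tether_weights=[w] * len(handles)))
        for w in (10.0, 3.0, 0.0)
    ]
    assert blocks[0] > blocks[1] > blocks[2] == 0.0


def test_chi2_additivity_over_blocks(small_case):
    pts = assemble_cartesian_points(
        small_case.reference, small_case.system, small_case.oracle_params
    )
    total = chi_squared(pts)
    by_kind = {}
    for p in pts:
        by_kind.setdefault(p.label[0], []).append(p)
    assert total == pytest.approx(
        sum(chi_squared(v) for v in by_kind.values()), rel=1e-12
    )


def test_zero_weight_elements_do_not_influence_chi2(small_case):
    """Perturbing only zero-weighted reference elements (the 1-1 diagonal
    blocks) leaves chi^2 unchanged."""
    ref = small_case.reference
    h2 = ref.hessian.copy()
    n = small_case.system.n_atoms
    for a in range(n):
        sl = slice(3 * a, 3 * a + 3)
        h2[sl, sl] += np.eye(3) * 17.0
    ref2 = ReferenceData(
        elements=ref.elements, coordinates=ref.coordinates, hessian=h2
    )
    obj1 = CartesianObjective(ref, small_case.system, small_case.oracle_params)
    obj2 = CartesianObjective(ref2, small_case.system, small_case.oracle_params)
    c1 = obj1.chi2(small_case.oracle_params)
    c2 = obj2.chi2(small_case.oracle_params)
    assert c2 == pytest.approx(c1, rel=1e-9)


def test_objective_weights_configurable(small_case):
    w = ObjectiveWeights(bond=0.0, angle=0.0, torsion=0.0, hessian=1.0)
    pts = assemble_cartesian_points(
        small_case.reference, small_case.system, small_case.oracle_params, w
    )
    geo = [p for p in pts if p.label[0] in ("bond", "angle", "torsion")]
    assert all(p.weight == 0.0 for p in geo)
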