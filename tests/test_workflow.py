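"""Staged fitting workflow: fixed point, stage mechanics, trace contracts."""

import numpy as np
import pytest

from tsffit.fitting import staged_fit
from tsffit.loopcfg import LoopConfig, RoundSpec, StageSpec
from tsffit.objective import CartesianObjective
from tsffit.synth import make_toy_ts, perturb_params


def _plain_config(kinds, optimizer="newton", max_iter=4, convergence=0.10,
                  max_cycles=3, mode="cartesian"):
    return LoopConfig(
        mode=mode,
        rounds=[
            RoundSpec(
                convergence=convergence,
                max_cycles=max_cycles,
                stages=[StageSpec(kinds=kinds, optimizer=optimizer,
                                  max_iter=max_iter)],
            )
        ],
    )


def test_oracle_start_is_a_fixed_point(small_case):
    """Against a reference whose Hessian is exactly the oracle Hessian
    (no planted negative mode), the oracle parameters are the optimum:
    the first macro-convergence check fires and the parameters come back
    essentially unchanged."""
    from tsffit.mm import Evaluator
    from tsffit.qmref import ReferenceData

    system = small_case.system
    h_oracle = Evaluator(system, small_case.oracle_params).hessian(
        system.coordinates
    )
    ref = ReferenceData(
        elements=[a.element for a in system.atoms],
        coordinates=system.coordinates,
        hessian=h_oracle,
    )
    cfg = _plain_config(["bond_k", "bond_r0", "angle_k", "angle_theta0"])
    fitted, trace = staged_fit(cfg, ref, system, small_case.oracle_params)
    for key, b in fitted.bond_terms.items():
        orig = small_case.oracle_params.bond_terms[key]
        assert b.k == pytest.approx(orig.k, rel=1e-2)
        assert b.r0 == pytest.approx(orig.r0, abs=1e-3)
    cycles = {r.stage.split("s")[0] for r in trace.records}
    assert cycles == {"r1c1"}  # converged after the first macro-cycle


def test_accepted_chi2_non_increasing_within_stages(small_case):
    start = perturb_params(small_case.oracle_params, seed=3, fraction=0.2)
    cfg = _plain_config(["bond_k", "angle_k"], max_iter=6)
    _, trace = staged_fit(cfg, small_case.reference, small_case.system, start)
    stages = {r.stage for r in trace.records}
    assert stages
    for st in stages:
        seq = trace.accepted_chi2(st)
        assert all(a >= b - 1e-12 for a, b in zip(seq, seq[1:]))


def test_simplex_stage_runs_and_improves(small_case):
    start = perturb_params(small_case.oracle_params, seed=4, fraction=0.2)
    cfg = _plain_config(["bond_r0"], optimizer="simplex", max_iter=60,
                        max_cycles=1)
    obj = CartesianObjective(small_case.reference, small_case.system, start)
    c0 = obj.chi2(start)
    fitted, trace = staged_fit(cfg, small_case.reference, small_case.system, start)
    assert obj.chi2(fitted) < c0
    assert any("simplex" in r.step_kind for r in trace.records)


def test_determinism_bit_identical_traces(small_case):
    start = perturb_params(small_case.oracle_params, seed=5, fraction=0.2)
    cfg = _plain_config(["bond_k"], max_iter=3, max_cycles=1)
    f1, t1 = staged_fit(cfg, small_case.reference, small_case.system, start)
    f2, t2 = staged_fit(cfg, small_case.reference, small_case.system, start)
    assert f1 == f2
    assert len(t1.records) == len(t2.records)
    for a, b in zip(t1.records, t2.records):
        assert a.chi2 == b.chi2 and np.array_equal(a.parameters, b.parameters)


def test_charges_and_lj_untouched(small_case):
    start = perturb_params(small_case.oracle_params, seed=6, fraction=0.2)
    fitted, _ = staged_fit(
        _plain_config(["bond_k"], max_iter=2, max_cycles=1),
        small_case.reference, small_case.system, start,
    )
    assert fitted.nonbonded == start.nonbonded
    assert fitted.masses == start.masses


def test_dihedral_zeroing_and_seeding(small_case):
    """Dihedral barriers are held at zero while force constants are fit,
    then restored from the input values (floored) for their own stage."""
    start = perturb_params(small_case.oracle_params, seed=7, fraction=0.2)
    cfg = LoopConfig(
        rounds=[
            RoundSpec(
                convergence=0.10,
                max_cycles=1,
                stages=[
                    StageSpec(kinds=["bond_k", "angle_k"], optimizer="newton",
                              max_iter=1, zero_dihedrals=True),
                ],
            )
        ]
    )
    fitted, _ = staged_fit(cfg, small_case.reference, small_case.system, start)
    assert all(
        t.barrier == 0.0 for ts in fitted.dihedral_terms.values() for t in ts
    )
    cfg2 = LoopConfig(
        rounds=[
            RoundSpec(
                convergence=0.10,
                max_cycles=1,
                stages=[
                    StageSpec(kinds=["bond_k"], optimizer="newton",
                              max_iter=1, zero_dihedrals=True),
                    StageSpec(kinds=["dihedral_V"], optimizer="newton",
                              max_iter=1, seed_dihedrals=True),
                ],
            )
        ]
    )
    fitted2, _ = staged_fit(cfg2, small_case.reference, small_case.system, start)
    assert all(
        t.barrier >= 3.2 for ts in fitted2.dihedral_terms.values() for t in ts
    )


def test_trace_persisted_on_stage_failure(tmp_path, small_case):
    start = perturb_params(small_case.oracle_params, seed=8, fraction=0.2)
    bad = LoopConfig(
        rounds=[
            RoundSpec(convergence=0.1, max_cycles=1,
                      stages=[StageSpec(kinds=["bond_k"], max_iter=1)])
        ],
        mode="cartesian",
    )
    # sabotage: drop an angle parameter the system needs -> stage raises
    broken = start.copy()
    broken.angle_terms.pop(next(iter(broken.angle_terms)))
    trace_path = tmp_path / "trace.tsv"
    with pytest.raises(Exception):
        staged_fit(bad, small_case.reference, small_case.system, broken,
                   trace_path=trace_path)
    assert trace_path.exists()


def test_eigenmode_mode_runs(small_case):
    start = perturb_params(small_case.oracle_params, seed=9, fraction=0.1)
    cfg = _plain_config(["bond_k"], max_iter=2, max_cycles=1, mode="eigenmode")
    from tsffit.objective import EigenmodeObjective

    obj = EigenmodeObjective(small_case.reference, small_case.system, start)
    c0 = obj.chi2(start)
    fitted, _ = staged_fit(cfg, small_case.reference, small_case.system, start)
    assert obj.chi2(fitted) <= c0


def test_tether_schedule_consumed_across_cycles(small_case):
    start = perturb_params(small_case.oracle_params, seed=10, fraction=0.2)
    cfg = LoopConfig(
        rounds=[
            RoundSpec(
                convergence=1e-6,  # force several cycles
                max_cycles=3,
                stages=[StageSpec(kinds=["angle_theta0"], optimizer="newton",
                                  max_iter=2, tether=[10.0, 3.0, 0.0])],
            )
        ]
    )
    fitted, trace = staged_fit(cfg, small_case.reference, small_case.system, start)
    cycles = sorted({r.stage.split("s")[0] for r in trace.records})
    assert len(cycles) >= 2  # schedule actually stepped through


def _raise_barriers(params):
    # keep every oracle barrier above the 3.2 kcal/mol optimization floor so
    # the floor constraint stays inactive and the oracle is feasible
    for terms in params.dihedral_terms.values():
        for t in terms:
            t.barrier = 3.3 + 0.4 * (t.barrier % 1.7)


@pytest.mark.parametrize("seed", range(1, 11))
def test_end_to_end_recovery_reaches_oracle_chi2_floor(seed):
    """With all bound floors inactive, a staged fit from 20%-perturbed
    parameters must come within 2x of the oracle-parameter chi^2 floor, and
    the fitted TSFF must satisfy the TS-as-minimum contract."""
    import warnings

    from conftest import SWEEP_SIZE

    case = make_toy_ts(seed=seed, size=SWEEP_SIZE, modify_params=_raise_barriers)
    start = perturb_params(case.oracle_params, seed=seed, fraction=0.2)
    obj = CartesianObjective(case.reference, case.system, case.oracle_params)
    obj.rebase(case.oracle_params)
    chi2_floor = obj.chi2(case.oracle_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted, _ = staged_fit(None, case.reference, case.system, start)
    obj.rebase(case.oracle_params)
    assert obj.chi2(fitted) <= 2.0 * chi2_floor
    import tsffit as tf

    res = tf.minimize(case.system, fitted, case.reference.coordinates)
    evals = np.linalg.eigvalsh(tf.Evaluator(case.system, fitted).hessian(res.coordinates))
    order = np.argsort(np.abs(evals))
    vib = [evals[k] for k in range(len(evals)) if k not in set(order[:6])]
    assert min(vib) >= -1.0


def test_frozen_terminals_leave_supported_parameters_stable(recovery_sweep):
    """Freezing the two chain-terminal atoms (zero-weighting their Hessian
    data) must not shift parameters that keep full data support by more than
    the fit's own seed-to-seed recovery spread. Parameters whose type keys
    touch the frozen atoms lose their Hessian data and are allowed to
    drift."""
    from conftest import fit_perturbed_case, pooled_recovery_errors, SWEEP_SIZE

    case_u, fit_u, _ = recovery_sweep[0]  # seed 1, unfrozen
    m = SWEEP_SIZE - max(0, (SWEEP_SIZE - 6) // 3)  # backbone length
    frozen_names = ["A1", f"A{m}"]
    _, fit_f, _ = fit_perturbed_case(1, frozen_names=frozen_names)
    frozen_types = {
        case_u.system.atoms[case_u.system.index_of(n)].atom_type
        for n in frozen_names
    }
    spread = float(np.quantile(pooled_recovery_errors(recovery_sweep), 0.95))
    changes = []
    for key in fit_u.bond_terms:
        if frozen_types & set(key):
            continue
        changes.append(
            abs(fit_f.bond_terms[key].k - fit_u.bond_terms[key].k)
            / fit_u.bond_terms[key].k
        )
    for key in fit_u.angle_terms:
        if frozen_types & set(key):
            continue
        changes.append(
            abs(fit_f.angle_terms[key].k - fit_u.angle_terms[key].k)
            / fit_u.angle_terms[key].k
        )
    assert changes
    assert max(changes) <= max(spread, 0.05)


def test_fit_trace_tsv_format(small_case):
    start = perturb_params(small_case.oracle_params, seed=11, fraction=0.15)
    _, trace = staged_fit(
        _plain_config(["bond_k"], max_iter=2, max_cycles=1),
        small_case.reference, small_case.system, start,
    )
    tsv = trace.to_tsv()
    header, *rows = tsv.strip().splitlines()
    assert header.split("\t") == [
        "stage", "iteration", "chi2", "step_kind", "accepted", "parameters"
    ]
    assert rows and all(len(r.split("\t")) == 6 for r in rows)
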