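import numpy as np
import pytest

from tsffit.frcmod import (
    AngleTerm,
    BondTerm,
    DihedralTerm,
    FrcmodParameterSet,
    NonbondedTerm,
)
from tsffit.structures import Atom, MolecularSystem
from tsffit.synth import make_toy_ts


def make_chain(n, types=None, coords=None):
    """Linear chain a1-a2-...-an with neutral charges."""
    types = types or [f"a{i}" for i in range(n)]
    atoms = [
        Atom(index=i, name=f"A{i + 1}", atom_type=types[i], element="C")
        for i in range(n)
    ]
    if coords is None:
        coords = np.column_stack(
            [1.5 * np.arange(n), 0.3 * (np.arange(n) % 2), np.zeros(n)]
        )
    bonds = [(i, i + 1) for i in range(n - 1)]
    return MolecularSystem(atoms=atoms, coordinates=coords, bonds=bonds)


def random_params(rng, n_bond=3, n_angle=2, n_dih=2, types=None):
    """Random but valid parameter set for round-trip tests."""
    p = FrcmodParameterSet(title="random fixture")
    types = types or [f"t{i}" for i in range(max(n_bond + 1, 4))]
    for t in types:
        p.masses[t] = float(np.round(rng.uniform(1, 35), 3))
        p.nonbonded[t] = NonbondedTerm(
            rmin_half=float(np.round(rng.uniform(1.2, 2.2), 4)),
            epsilon=float(np.round(rng.uniform(0.01, 0.3), 4)),
        )
    for i in range(n_bond):
        p.bond_terms[(types[i], types[i + 1])] = BondTerm(
            k=float(np.round(rng.uniform(100, 600), 2)),
            r0=float(np.round(rng.uniform(1.0, 1.8), 4)),
        )
    for i in range(n_angle):
        p.angle_terms[(types[i], types[i + 1], types[(i + 2) % len(types)])] = (
            AngleTerm(
                k=float(np.round(rng.uniform(30, 120), 2)),
                theta0=float(np.round(rng.uniform(90, 150), 3)),
            )
        )
    for i in range(n_dih):
        nterms = int(rng.integers(1, 3))
        key = (types[i], types[i + 1], types[(i + 2) % len(types)],
               types[(i + 3) % len(types)])
        p.dihedral_terms[key] = [
            DihedralTerm(
                divider=int(rng.integers(1, 4)),
                barrier=float(np.round(rng.uniform(0, 10), 2)),
                phase=float(np.round(rng.choice([0.0, 180.0]), 3)),
                periodicity=int(rng.integers(1, 5)),
            )
            for _ in range(nterms)
        ]
    return p


@pytest.fixture(scope="session")
def toy_case():
    """One mid-size synthetic TS case shared by read-only tests."""
    return make_toy_ts(seed=11, size=12)


N_SWEEP_SEEDS = 10
SWEEP_SIZE = 12


def fit_perturbed_case(seed, modify_params=None, frozen_names=None):
    """Generate a synthetic case and run the default staged fit from a
    20%-perturbed start. Returns (case, fitted params, trace)."""
    import warnings

    from tsffit.fitting import staged_fit
    from tsffit.synth import perturb_params

    case = make_toy_ts(seed=seed, size=SWEEP_SIZE, modify_params=modify_params)
    if frozen_names:
        for name in frozen_names:
            case.system.frozen[case.system.index_of(name)] = True
    start = perturb_params(case.oracle_params, seed=seed, fraction=0.2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted, trace = staged_fit(None, case.reference, case.system, start)
    return case, fitted, trace


@pytest.fixture(scope="session")
def recovery_sweep():
    """Ten staged fits from 20%-perturbed oracle parameters under the
    default study conditions; shared by the TS-as-minimum, recovery,
    trace-monotonicity and frozen-atom tests."""
    return [fit_perturbed_case(seed) for seed in range(1, N_SWEEP_SEEDS + 1)]


def pooled_recovery_errors(sweep):
    """Relative force-constant recovery errors pooled over a sweep."""
    errs = []
    for case, fitted, _ in sweep:
        op = case.oracle_params
        for key, b in fitted.bond_terms.items():
            errs.append(abs(b.k - op.bond_terms[key].k) / op.bond_terms[key].k)
        for key, a in fitted.angle_terms.items():
            errs.append(abs(a.k - op.angle_terms[key].k) / op.angle_terms[key].k)
    return np.array(errs)


@pytest.fixture(scope="session")
def small_case():
    """A small, fast case for workflow tests."""
    return make_toy_ts(seed=5, size=8)
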