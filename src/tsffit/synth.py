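"""Synthetic transition-state-like model systems with known (oracle)
parameters and a manufactured reference Hessian.

A toy case emulates the training data of a real fit without any QM code: a
donor-H-acceptor chain plus spectator branch atoms gets chemically plausible
oracle parameters, the geometry is minimized under the oracle potential, and
the oracle Hessian's softest vibrational eigenvalue is replaced by a
negative curvature before reconstructing H_ref = V E' V^T. The result looks
like a first-order saddle to every consumer (exactly one significant
negative eigenvalue, reaction vector attached) while the generating
parameters remain known, so parameter-recovery experiments have a ground
truth.

What this emulates: TS geometry + Hessian of a vacuum cluster with fixed
charges. What it does not: electronic reorganization (the oracle potential
IS an Amber form, so the functional-form mismatch of real QM data is absent),
solvent, and frozen-atom Hessian artifacts (frozen flags can be added but
the reference Hessian here is physical everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frcmod import (
    AngleTerm,
    BondTerm,
    DihedralTerm,
    FrcmodParameterSet,
    NonbondedTerm,
    write_frcmod,
)
from .loopcfg import LoopConfig, default_stage_program, write_loop_config
from .mm import Evaluator, minimize
from .qmref import ReferenceData, write_archive, _NUMBERS
from .structures import (
    Atom,
    MolecularSystem,
    write_charge_library,
    write_pdb,
)
from .topology import enumerate_internals

__all__ = [
    "SyntheticCase",
    "make_toy_ts",
    "perturb_params",
    "write_reference_archive",
    "write_synthetic_log",
    "write_case_files",
]

_ELEMENT_MASS = {"H": 1.008, "C": 12.01, "N": 14.01, "O": 16.00}

# bounds mirrored from the fitting module (import would be circular)
_K_FLOOR = 32.2
_V_FLOOR = 3.2


@dataclass
class SyntheticCase:
    system: MolecularSystem
    oracle_params: FrcmodParameterSet
    reference: ReferenceData
    reaction_vector: np.ndarray
    seed: int


def _type_name(i: int) -> str:
    return chr(ord("a") + i // 26) + chr(ord("a") + i % 26)


def _build_topology(seed: int, size: int, rng: np.random.Generator):
    n_branch = max(0, (size - 6) // 3)
    m = size - n_branch  # backbone length
    h_index = m // 2     # the transferred hydrogen
    elements = []
    for i in range(m):
        if i == h_index:
            elements.append("H")
        else:
            elements.append(str(rng.choice(["C", "C", "N", "O"])))
    bonds = [(i, i + 1) for i in range(m - 1)]
    # spectator branches on interior heavy atoms (never on the transferred H)
    hosts = [i for i in range(1, m - 1) if i != h_index]
    for b in range(n_branch):
        parent = int(rng.choice(hosts))
        idx = m + b
        elements.append("H")
        bonds.append((parent, idx))
    types = [_type_name(i) for i in range(size)]
    names = [f"A{i + 1}" for i in range(size)]
    return elements, types, names, bonds, h_index, m


def _draw_params(system, elements, rng: np.random.Generator, h_index: int):
    params = FrcmodParameterSet(title="synthetic oracle parameters")
    types = system.atom_types
    for t, el in zip(types, elements):
        params.masses[t] = _ELEMENT_MASS[el]
        if el == "H":
            params.nonbonded[t] = NonbondedTerm(
                rmin_half=float(rng.uniform(1.3, 1.5)),
                epsilon=float(rng.uniform(0.02, 0.06)),
            )
        else:
            params.nonbonded[t] = NonbondedTerm(
                rmin_half=float(rng.uniform(1.7, 2.0)),
                epsilon=float(rng.uniform(0.05, 0.15)),
            )
    table = enumerate_internals(system)
    for i, j in table.bonds:
        any_h = "H" in (elements[i], elements[j])
        params.bond_terms[(types[i], types[j])] = BondTerm(
            k=float(rng.uniform(250.0, 400.0)),
            r0=float(rng.uniform(1.10, 1.30) if any_h else rng.uniform(1.35, 1.55)),
        )
    for i, j, k in table.angles:
        # the donor-H-acceptor angle is opened toward linear, as in a
        # hydride-transfer TS, but kept off 180 deg
        theta0 = (
            rng.uniform(150.0, 165.0) if j == h_index else rng.uniform(105.0, 125.0)
        )
        params.angle_terms[(types[i], types[j], types[k])] = AngleTerm(
            k=float(rng.uniform(40.0, 80.0)), theta0=float(theta0)
        )
    for quad in table.torsions:
        key = tuple(types[a] for a in quad)
        params.dihedral_terms[key] = [
            DihedralTerm(
                divider=1,
                barrier=float(rng.uniform(0.0, 5.0)),
                phase=0.0,
                periodicity=int(rng.choice([2, 3])),
            )
        ]
    return params


def _initial_coords(size, bonds, m, rng: np.random.Generator):
    x = np.zeros((size, 3))
    for i in range(m):
        x[i] = [1.45 * i, 0.45 * (i % 2), 0.0]
    for i, j in bonds:
        if j >= m:  # branch atom j attached to parent i
            off = rng.normal(size=3)
            off[0] *= 0.3
            off = off / np.linalg.norm(off)
            x[j] = x[i] + 1.1 * off
    x += rng.normal(scale=0.05, size=x.shape)
    return x


def make_toy_ts(
    seed: int,
    size: int = 12,
    neg_curvature: float = 150.0,
    modify_params=None,
) -> SyntheticCase:
    """Generate a synthetic TS-like case.

    ``modify_params(params)`` may edit the oracle parameter set before the
    geometry is minimized and the reference Hessian manufactured (used to
    plant, e.g., an implausibly soft oracle force constant).

    The softest non-translational/rotational eigenvalue of the oracle
    Hessian is replaced by ``-neg_curvature`` (default 150 kcal/mol/A^2, a
    typical hydride-transfer curvature scale) and the Hessian is
    reconstructed in the oracle eigenbasis.
    """
    if size < 4:
        raise ValueError("size must be at least 4")
    last_err = None
    for attempt in range(10):
        rng = np.random.default_rng((seed + 7919 * attempt) % 2**31)
        elements, types, names, bonds, h_index, m = _build_topology(seed, size, rng)
        charges = rng.normal(scale=0.08, size=size)
        charges -= charges.mean()
        charges = np.round(charges, 6)
        charges[-1] -= charges.sum()
        atoms = [
            Atom(index=i, name=names[i], atom_type=types[i], element=elements[i],
                 charge=float(charges[i]))
            for i in range(size)
        ]
        coords0 = _initial_coords(size, bonds, m, rng)
        system = MolecularSystem(atoms=atoms, coordinates=coords0, bonds=bonds)
        params = _draw_params(system, elements, rng, h_index)
        if modify_params is not None:
            modify_params(params)
        ev = Evaluator(system, params)
        res = minimize(system, params, coords0, evaluator=ev)
        if not res.converged:
            last_err = RuntimeError(
                f"oracle minimization did not converge (seed {seed}, "
                f"attempt {attempt}, rms grad {res.rms_gradient:.2e})"
            )
            continue
        system.coordinates = res.coordinates
        h = ev.hessian(res.coordinates)
        evals, vecs = np.linalg.eigh(h)
        order = np.argsort(np.abs(evals))
        trans_rot = set(order[:6].tolist())
        vib = [k for k in range(len(evals)) if k not in trans_rot]
        k_soft = min(vib, key=lambda k: evals[k])
        e_mod = evals.copy()
        e_mod[k_soft] = -float(neg_curvature)
        h_ref = vecs @ np.diag(e_mod) @ vecs.T
        h_ref = 0.5 * (h_ref + h_ref.T)
        reference = ReferenceData(
            elements=list(elements), coordinates=res.coordinates, hessian=h_ref
        )
        return SyntheticCase(
            system=system,
            oracle_params=params,
            reference=reference,
            reaction_vector=vecs[:, k_soft].copy(),
            seed=seed,
        )
    raise last_err


_PERTURB_BOUNDS = {
    # (multiplicative, lower, upper); angles are perturbed additively
    "bond_k": (True, _K_FLOOR, 5000.0),
    "bond_r0": (True, 0.5, 3.5),
    "angle_k": (True, _K_FLOOR, 2000.0),
    "angle_theta0": (False, 1e-3, 180.0),
    "dihedral_V": (True, _V_FLOOR, 200.0),
}


def perturb_params(
    params: FrcmodParameterSet, seed: int, fraction: float = 0.2
) -> FrcmodParameterSet:
    """Multiply each optimizable value by (1 + u), u ~ U[-fraction, fraction]
    (equilibrium angles move additively by up to fraction x 20 deg), then
    clamp to the fitting bounds. Emulates the crude starting values a fit
    begins from."""
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    out = params.copy()

    def jitter(v, mult, lo, hi, scale=1.0):
        if mult:
            v = v * (1.0 + rng.uniform(-fraction, fraction))
        else:
            v = v + rng.uniform(-fraction, fraction) * 20.0
        return float(np.clip(v, lo, hi))

    for b in out.bond_terms.values():
        b.k = jitter(b.k, *_PERTURB_BOUNDS["bond_k"])
        b.r0 = jitter(b.r0, *_PERTURB_BOUNDS["bond_r0"])
    for a in out.angle_terms.values():
        a.k = jitter(a.k, *_PERTURB_BOUNDS["angle_k"])
        a.theta0 = jitter(a.theta0, *_PERTURB_BOUNDS["angle_theta0"])
    for terms in out.dihedral_terms.values():
        for t in terms:
            t.barrier = jitter(t.barrier, *_PERTURB_BOUNDS["dihedral_V"])
    return out


def write_reference_archive(case: SyntheticCase) -> str:
    """Serialize the case's reference data to the archive text format."""
    return write_archive(case.reference)


def write_synthetic_log(elements, coordinates, hessian_kcal) -> str:
    """Emit a minimal QM-log dialect (geometry table in A + lower-triangular
    Cartesian force constants in Hartree/Bohr^2) that ``parse_qm_log`` reads
    back losslessly up to the unit round-trip."""
    from .qmref import HESSIAN_UNIT_FACTOR

    coords = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    h_au = np.asarray(hessian_kcal, dtype=float) / HESSIAN_UNIT_FACTOR
    n = len(elements)
    dim = 3 * n
    out = [
        " Synthetic transition-state log (tsffit)",
        "                          Input orientation:",
        " ---------------------------------------------------------------------",
        " Center     Atomic      Atomic             Coordinates (Angstroms)",
        " Number     Number       Type             X           Y           Z",
        " ---------------------------------------------------------------------",
    ]
    for i, (el, xyz) in enumerate(zip(elements, coords), start=1):
        z = _NUMBERS.get(el, 6)
        out.append(
            f" {i:6d} {z:10d} {0:11d}    {xyz[0]:11.6f} {xyz[1]:11.6f} {xyz[2]:11.6f}"
        )
    out.append(" ---------------------------------------------------------------------")
    out.append(" Force constants in Cartesian coordinates: ")

    def dfmt(v):
        s = f"{v:.8E}"
        mant, ex = s.split("E")
        return f"{mant}D{int(ex):+03d}"

    for c0 in range(0, dim, 5):
        cols = list(range(c0, min(c0 + 5, dim)))
        out.append("".join(f"{c + 1:14d}" for c in cols))
        for row in range(c0, dim):
            vals = [h_au[row, c] for c in cols if c <= row]
            out.append(
                f"{row + 1:7d}" + "".join(f"  {dfmt(v)}" for v in vals)
            )
    out.append(" end of synthetic log")
    return "\n".join(out) + "\n"


def write_case_files(case: SyntheticCase, out_dir, fraction: float = 0.2) -> dict:
    """Write the full input bundle a fit needs: structure (PDB), charge/
    connectivity library, frozen-atom list (empty), perturbed starting
    frcmod, oracle frcmod (for scoring only), reference archive, loop
    config. Returns the path map."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = perturb_params(case.oracle_params, seed=case.seed, fraction=fraction)
    paths = {
        "structure": out / "structure.pdb",
        "charges": out / "charges.lib",
        "frozen": out / "fixedatoms.txt",
        "frcmod": out / "initial.frcmod",
        "oracle": out / "oracle.frcmod",
        "reference": out / "reference.qref",
        "loop": out / "loop.in",
    }
    paths["structure"].write_text(write_pdb(case.system))
    paths["charges"].write_text(write_charge_library(case.system))
    paths["frozen"].write_text("# one frozen atom name per line\n")
    paths["frcmod"].write_text(write_frcmod(start))
    paths["oracle"].write_text(write_frcmod(case.oracle_params))
    paths["reference"].write_text(write_reference_archive(case))
    config = LoopConfig(
        rounds=default_stage_program(),
        mode="cartesian",
        seed=case.seed,
        ffld="initial.frcmod",
        rdat="reference.qref",
        structure="structure.pdb",
        charges="charges.lib",
        frozen="fixedatoms.txt",
    )
    paths["loop"].write_text(write_loop_config(config))
    return {k: str(v) for k, v in paths.items()}
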