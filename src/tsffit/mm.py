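"""Amber-functional-form potential: energy, analytic gradient, Hessian,
and geometry minimization.

    E = sum k_b (r - r0)^2 + sum k_th (theta - theta0)^2
      + sum (V_n / divider) (1 + cos(n phi - gamma))
      + LJ 12-6 + Coulomb

with 1-2 and 1-3 nonbonded exclusions and Amber 1-4 scaling (electrostatics
/ 1.2, Lennard-Jones / 2.0). No cutoffs and no periodicity: the model
systems are vacuum clusters of a few hundred atoms at most, so all pairs
are evaluated. Angle math is in radians internally; frcmod files carry
degrees for equilibrium angles and phases.

The Hessian is a central finite difference of the analytic gradient
(default step 1e-4 A), symmetrized. Frozen atoms still receive gradient and
Hessian entries; freezing is enforced by the minimizer and by the
objective's weights, not by the potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .frcmod import FrcmodParameterSet
from .structures import MolecularSystem
from .topology import enumerate_internals, separation_matrix

__all__ = [
    "COULOMB_FACTOR",
    "SCEE",
    "SCNB",
    "ParameterLookupError",
    "EnergyReport",
    "Evaluator",
    "energy",
    "gradient",
    "hessian",
    "minimize",
    "MinimizationResult",
    "rmsd",
]

COULOMB_FACTOR = 332.0637128  # kcal/mol * A / e^2
SCEE = 1.2                    # 1-4 electrostatic divisor
SCNB = 2.0                    # 1-4 Lennard-Jones divisor


class ParameterLookupError(KeyError):
    """An internal coordinate has no matching frcmod entry."""


def _lookup_bond(params, ti, tj):
    for key in ((ti, tj), (tj, ti)):
        if key in params.bond_terms:
            return key
    raise ParameterLookupError(f"no bond parameter for type key {ti}-{tj}")


def _lookup_angle(params, ti, tj, tk):
    for key in ((ti, tj, tk), (tk, tj, ti)):
        if key in params.angle_terms:
            return key
    raise ParameterLookupError(f"no angle parameter for type key {ti}-{tj}-{tk}")


def _lookup_dihedral(params, ti, tj, tk, tl):
    candidates = (
        (ti, tj, tk, tl),
        (tl, tk, tj, ti),
        ("X", tj, tk, "X"),
        ("X", tk, tj, "X"),
    )
    for key in candidates:
        if key in params.dihedral_terms:
            return key
    raise ParameterLookupError(
        f"no dihedral parameter for type key {ti}-{tj}-{tk}-{tl}"
    )


@dataclass
class EnergyReport:
    total: float
    bond: float
    angle: float
    dihedral: float
    improper: float
    vdw: float
    electrostatic: float

    @property
    def components(self) -> dict[str, float]:
        return {
            "bond": self.bond,
            "angle": self.angle,
            "dihedral": self.dihedral,
            "improper": self.improper,
            "vdw": self.vdw,
            "electrostatic": self.electrostatic,
        }


def _match_impropers(system: MolecularSystem, params: FrcmodParameterSet):
    """Quadruples (i, j, c, l) for improper keys; third atom is central
    (Amber convention). Only types named in the parameter file are used."""
    if not params.improper_terms:
        return []
    from itertools import permutations

    neighbors: dict[int, list[int]] = {i: [] for i in range(system.n_atoms)}
    for i, j in system.bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    types = system.atom_types
    found = []
    seen = set()
    for key in params.improper_terms:
        t1, t2, tc, t4 = key
        for c in range(system.n_atoms):
            if types[c] != tc or len(neighbors[c]) < 3:
                continue
            for a, b, d in permutations(sorted(neighbors[c]), 3):
                want = (t1, t2, t4)
                have = (types[a], types[b], types[d])
                ok = all(w in ("X", h) for w, h in zip(want, have))
                if ok:
                    quad = (a, b, c, d)
                    tag = (c, frozenset((a, b, d)), key)
                    if tag not in seen:
                        seen.add(tag)
                        found.append((quad, key))
                    break
    return found


class Evaluator:
    """Caches index arrays and parameter arrays for fast repeated evaluation.

    ``refresh(params)`` re-reads parameter values without re-deriving the
    topology, which is what makes the fitting loop affordable.
    """

    def __init__(
        self,
        system: MolecularSystem,
        params: FrcmodParameterSet,
        *,
        scee: float = SCEE,
        scnb: float = SCNB,
    ):
        self.system = system
        self.scee = scee
        self.scnb = scnb
        table = enumerate_internals(system)
        self.internals = table
        types = system.atom_types

        self._bond_idx = np.array(table.bonds, dtype=int).reshape(-1, 2)
        self._bond_keys = [
            _lookup_bond(params, types[i], types[j]) for i, j in table.bonds
        ]
        self._angle_idx = np.array(table.angles, dtype=int).reshape(-1, 3)
        self._angle_keys = [
            _lookup_angle(params, types[i], types[j], types[k])
            for i, j, k in table.angles
        ]
        # torsions expand to one row per Fourier term
        tor_rows, tor_refs = [], []
        for quad in table.torsions:
            key = _lookup_dihedral(params, *(types[a] for a in quad))
            for t_idx in range(len(params.dihedral_terms[key])):
                tor_rows.append(quad)
                tor_refs.append((key, t_idx))
        self._tor_idx = np.array(tor_rows, dtype=int).reshape(-1, 4)
        self._tor_refs = tor_refs
        imp_rows, imp_refs = [], []
        for quad, key in _match_impropers(system, params):
            for t_idx in range(len(params.improper_terms[key])):
                imp_rows.append(quad)
                imp_refs.append((key, t_idx))
        self._imp_idx = np.array(imp_rows, dtype=int).reshape(-1, 4)
        self._imp_refs = imp_refs

        self._build_pairs(system, params)
        self.refresh(params)

    def _build_pairs(self, system, params):
        n = system.n_atoms
        sep = separation_matrix(system)
        iu, ju = np.triu_indices(n, k=1)
        s = sep[iu, ju]
        keep = (s < 0) | (s >= 3)  # exclude 1-2 and 1-3
        self._pair_i = iu[keep]
        self._pair_j = ju[keep]
        scale14 = s[keep] == 3
        self._ee_scale = np.where(scale14, 1.0 / self.scee, 1.0)
        self._lj_scale = np.where(scale14, 1.0 / self.scnb, 1.0)
        q = system.charges
        self._qq = COULOMB_FACTOR * q[self._pair_i] * q[self._pair_j] * self._ee_scale

    def refresh(self, params: FrcmodParameterSet) -> None:
        """Reload parameter values (topology and keys unchanged)."""
        self._bk = np.array([params.bond_terms[k].k for k in self._bond_keys])
        self._br0 = np.array([params.bond_terms[k].r0 for k in self._bond_keys])
        self._ak = np.array([params.angle_terms[k].k for k in self._angle_keys])
        self._ath0 = np.radians(
            [params.angle_terms[k].theta0 for k in self._angle_keys]
        )
        def _terms(table, refs):
            v = np.array([table[k][t].barrier / table[k][t].divider for k, t in refs])
            n_ = np.array([float(table[k][t].periodicity) for k, t in refs])
            g = np.radians([table[k][t].phase for k, t in refs])
            return v, n_, g

        self._tv, self._tn, self._tg = _terms(params.dihedral_terms, self._tor_refs)
        self._iv, self._in, self._ig = _terms(params.improper_terms, self._imp_refs)

        types = self.system.atom_types
        missing = [t for t in set(types) if t not in params.nonbonded]
        if missing:
            raise ParameterLookupError(f"no NONBON parameters for types {missing}")
        rh = np.array([params.nonbonded[t].rmin_half for t in types])
        ep = np.array([params.nonbonded[t].epsilon for t in types])
        rmin = rh[self._pair_i] + rh[self._pair_j]
        eps = np.sqrt(ep[self._pair_i] * ep[self._pair_j]) * self._lj_scale
        self._ljA = eps * rmin**12
        self._ljB = 2.0 * eps * rmin**6

    # --- geometry helpers -------------------------------------------------

    @staticmethod
    def _dihedral_geometry(x, idx):
        b1 = x[idx[:, 1]] - x[idx[:, 0]]
        b2 = x[idx[:, 2]] - x[idx[:, 1]]
        b3 = x[idx[:, 3]] - x[idx[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.where(nb2 > 0, nb2, 1.0)
        xx = np.einsum("ij,ij->i", n1, n2)
        return np.arctan2(y, xx), b1, b2, b3, n1, n2, nb2

    def _torsion_energy_grad(self, x, idx, v, per, gam, grad):
        if idx.shape[0] == 0:
            return 0.0
        phi, b1, b2, b3, n1, n2, nb2 = self._dihedral_geometry(x, idx)
        arg = per * phi - gam
        e = float(np.sum(v * (1.0 + np.cos(arg))))
        if grad is not None:
            dE = -v * per * np.sin(arg)
            sq1 = np.einsum("ij,ij->i", n1, n1)
            sq2 = np.einsum("ij,ij->i", n2, n2)
            fi = -(nb2 / sq1)[:, None] * n1
            fl = (nb2 / sq2)[:, None] * n2
            p = (np.einsum("ij,ij->i", b1, b2) / nb2**2)[:, None]
            q = (np.einsum("ij,ij->i", b3, b2) / nb2**2)[:, None]
            fj = -(1.0 + p) * fi + q * fl
            fk = p * fi - (1.0 + q) * fl
            for col, f in zip(idx.T, (fi, fj, fk, fl)):
                np.add.at(grad, col, dE[:, None] * f)
        return e

    # --- evaluation -------------------------------------------------------

    def energy_report(self, coords, _grad=None) -> EnergyReport:
        x = np.asarray(coords, dtype=float).reshape(-1, 3)
        grad = _grad

        # bonds
        d = x[self._bond_idx[:, 0]] - x[self._bond_idx[:, 1]]
        r = np.linalg.norm(d, axis=1)
        dr = r - self._br0
        e_bond = float(np.sum(self._bk * dr**2))
        if grad is not None and len(r):
            f = (2.0 * self._bk * dr / r)[:, None] * d
            np.add.at(grad, self._bond_idx[:, 0], f)
            np.add.at(grad, self._bond_idx[:, 1], -f)

        # angles
        e_angle = 0.0
        if self._angle_idx.shape[0]:
            u = x[self._angle_idx[:, 0]] - x[self._angle_idx[:, 1]]
            w = x[self._angle_idx[:, 2]] - x[self._angle_idx[:, 1]]
            nu = np.linalg.norm(u, axis=1)
            nw = np.linalg.norm(w, axis=1)
            cos = np.einsum("ij,ij->i", u, w) / (nu * nw)
            cos = np.clip(cos, -1.0, 1.0)
            theta = np.arccos(cos)
            dth = theta - self._ath0
            e_angle = float(np.sum(self._ak * dth**2))
            if grad is not None:
                sin = np.sqrt(np.maximum(1.0 - cos**2, 1e-12))
                dE = 2.0 * self._ak * dth
                gi = (cos[:, None] * u / nu[:, None] - w / nw[:, None]) / (
                    nu * sin
                )[:, None]
                gk = (cos[:, None] * w / nw[:, None] - u / nu[:, None]) / (
                    nw * sin
                )[:, None]
                gj = -(gi + gk)
                for col, gterm in zip(self._angle_idx.T, (gi, gj, gk)):
                    np.add.at(grad, col, dE[:, None] * gterm)

        e_dih = self._torsion_energy_grad(
            x, self._tor_idx, self._tv, self._tn, self._tg, grad
        )
        e_imp = self._torsion_energy_grad(
            x, self._imp_idx, self._iv, self._in, self._ig, grad
        )

        # nonbonded
        e_vdw = e_ee = 0.0
        if len(self._pair_i):
            dp = x[self._pair_i] - x[self._pair_j]
            r2 = np.einsum("ij,ij->i", dp, dp)
            inv2 = 1.0 / r2
            inv6 = inv2**3
            rinv = np.sqrt(inv2)
            e_vdw = float(np.sum(self._ljA * inv6**2 - self._ljB * inv6))
            e_ee = float(np.sum(self._qq * rinv))
            if grad is not None:
                # dE/dr * (1/r) premultiplied
                coef = (
                    -12.0 * self._ljA * inv6**2 + 6.0 * self._ljB * inv6
                ) * inv2 - self._qq * rinv * inv2
                f = coef[:, None] * dp
                np.add.at(grad, self._pair_i, f)
                np.add.at(grad, self._pair_j, -f)

        total = e_bond + e_angle + e_dih + e_imp + e_vdw + e_ee
        return EnergyReport(
            total=total,
            bond=e_bond,
            angle=e_angle,
            dihedral=e_dih,
            improper=e_imp,
            vdw=e_vdw,
            electrostatic=e_ee,
        )

    def energy(self, coords) -> float:
        return self.energy_report(coords).total

    def gradient(self, coords):
        """Returns (energy, gradient) with gradient shaped (N, 3)."""
        x = np.asarray(coords, dtype=float).reshape(-1, 3)
        g = np.zeros_like(x)
        rep = self.energy_report(x, _grad=g)
        return rep.total, g

    def gradient_batch(self, X: np.ndarray) -> np.ndarray:
        """Analytic gradient for a batch of configurations, shape (B, N, 3)."""
        X = np.asarray(X, dtype=float)
        B, N, _ = X.shape
        g = np.zeros((B * N, 3))
        offs = (np.arange(B) * N)[:, None]

        def scatter(cols, vals):
            np.add.at(g, (offs + cols[None, :]).ravel(), vals.reshape(-1, 3))

        if self._bond_idx.shape[0]:
            bi, bj = self._bond_idx[:, 0], self._bond_idx[:, 1]
            d = X[:, bi] - X[:, bj]
            r = np.linalg.norm(d, axis=2)
            f = (2.0 * self._bk * (r - self._br0) / r)[..., None] * d
            scatter(bi, f)
            scatter(bj, -f)

        if self._angle_idx.shape[0]:
            ai, aj, ak = (self._angle_idx[:, c] for c in range(3))
            u = X[:, ai] - X[:, aj]
            w = X[:, ak] - X[:, aj]
            nu = np.linalg.norm(u, axis=2)
            nw = np.linalg.norm(w, axis=2)
            cos = np.clip(np.einsum("bij,bij->bi", u, w) / (nu * nw), -1.0, 1.0)
            theta = np.arccos(cos)
            sin = np.sqrt(np.maximum(1.0 - cos**2, 1e-12))
            dE = 2.0 * self._ak * (theta - self._ath0)
            gi = (cos[..., None] * u / nu[..., None] - w / nw[..., None]) / (
                nu * sin
            )[..., None]
            gk = (cos[..., None] * w / nw[..., None] - u / nu[..., None]) / (
                nw * sin
            )[..., None]
            scatter(ai, dE[..., None] * gi)
            scatter(ak, dE[..., None] * gk)
            scatter(aj, -dE[..., None] * (gi + gk))

        for idx, v, per, gam in (
            (self._tor_idx, self._tv, self._tn, self._tg),
            (self._imp_idx, self._iv, self._in, self._ig),
        ):
            if idx.shape[0] == 0:
                continue
            b1 = X[:, idx[:, 1]] - X[:, idx[:, 0]]
            b2 = X[:, idx[:, 2]] - X[:, idx[:, 1]]
            b3 = X[:, idx[:, 3]] - X[:, idx[:, 2]]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=2)
            y = np.einsum("bij,bij->bi", np.cross(n1, n2), b2) / np.where(
                nb2 > 0, nb2, 1.0
            )
            xx = np.einsum("bij,bij->bi", n1, n2)
            phi = np.arctan2(y, xx)
            dE = -v * per * np.sin(per * phi - gam)
            sq1 = np.einsum("bij,bij->bi", n1, n1)
            sq2 = np.einsum("bij,bij->bi", n2, n2)
            fi = -(nb2 / sq1)[..., None] * n1
            fl = (nb2 / sq2)[..., None] * n2
            p = (np.einsum("bij,bij->bi", b1, b2) / nb2**2)[..., None]
            q = (np.einsum("bij,bij->bi", b3, b2) / nb2**2)[..., None]
            fj = -(1.0 + p) * fi + q * fl
            fk = p * fi - (1.0 + q) * fl
            for col, f in zip(idx.T, (fi, fj, fk, fl)):
                scatter(col, dE[..., None] * f)

        if len(self._pair_i):
            dp = X[:, self._pair_i] - X[:, self._pair_j]
            r2 = np.einsum("bij,bij->bi", dp, dp)
            inv2 = 1.0 / r2
            inv6 = inv2**3
            coef = (
                -12.0 * self._ljA * inv6**2 + 6.0 * self._ljB * inv6
            ) * inv2 - self._qq * np.sqrt(inv2) * inv2
            f = coef[..., None] * dp
            scatter(self._pair_i, f)
            scatter(self._pair_j, -f)

        return g.reshape(B, N, 3)

    def hessian(self, coords, step: float = 1e-4) -> np.ndarray:
        """Central finite difference of the analytic gradient, symmetrized.

        All 6N displaced configurations are evaluated as one batched
        gradient call (chunked to bound memory on large systems).
        """
        x = np.asarray(coords, dtype=float).reshape(-1)
        n3 = x.size
        disp = np.tile(x, (2 * n3, 1))
        rows = np.arange(n3)
        disp[2 * rows, rows] += step
        disp[2 * rows + 1, rows] -= step
        n_items = max(len(self._pair_i), self._tor_idx.shape[0], n3, 1)
        chunk = max(1, int(4_000_000 // n_items))
        grads = np.empty((2 * n3, n3))
        for s in range(0, 2 * n3, chunk):
            batch = disp[s : s + chunk].reshape(-1, n3 // 3, 3)
            grads[s : s + chunk] = self.gradient_batch(batch).reshape(-1, n3)
        h = (grads[2 * rows] - grads[2 * rows + 1]).T / (2.0 * step)
        return 0.5 * (h + h.T)


@dataclass
class MinimizationResult:
    coordinates: np.ndarray
    energy: float
    converged: bool
    n_iterations: int
    rms_gradient: float


def energy(system, params, coords) -> EnergyReport:
    return Evaluator(system, params).energy_report(coords)


def gradient(system, params, coords):
    return Evaluator(system, params).gradient(coords)[1]


def hessian(system, params, coords, step: float = 1e-4) -> np.ndarray:
    return Evaluator(system, params).hessian(coords, step=step)


def minimize(
    system,
    params,
    start,
    frozen=None,
    *,
    rms_gtol: float = 1e-5,
    maxiter: int = 5000,
    evaluator: Evaluator | None = None,
) -> MinimizationResult:
    """Quasi-Newton (L-BFGS-B) minimization over free atoms.

    Frozen atoms keep their starting coordinates bit-identically: their
    degrees of freedom are simply not exposed to the optimizer.
    Non-convergence is reported in the result, never raised.
    """
    ev = evaluator if evaluator is not None else Evaluator(system, params)
    x0 = np.asarray(start, dtype=float).reshape(-1, 3).copy()
    if frozen is None:
        frozen = system.frozen
    frozen = np.asarray(frozen, dtype=bool)
    free = ~np.repeat(frozen, 3)

    coords = x0.copy()

    def fun(z):
        coords.reshape(-1)[free] = z
        e, g = ev.gradient(coords)
        return e, g.reshape(-1)[free]

    res = _scipy_minimize(
        fun,
        x0.reshape(-1)[free],
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-9, "maxcor": 30},
    )
    coords.reshape(-1)[free] = res.x
    e, g = ev.gradient(coords)
    gfree = g.reshape(-1)[free]
    rms = float(np.sqrt(np.mean(gfree**2))) if gfree.size else 0.0
    return MinimizationResult(
        coordinates=coords,
        energy=e,
        converged=rms < rms_gtol,
        n_iterations=int(res.nit),
        rms_gradient=rms,
    )


def rmsd(a, b) -> float:
    """Plain (unaligned) all-atom RMSD in Angstrom."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
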