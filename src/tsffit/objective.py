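"""Weighted least-squares objective for force-field fitting.

The penalty function is

    chi^2 = sum_i w_i^2 (x_i^0 - x_i)^2

over data points pairing a reference value x^0 (from the QM TS calculation)
with the force-field value x. Two Hessian formulations are supported:

* Cartesian-Hessian mode — one point per unique Hessian element (i <= j),
  weighted by the topological factor from :mod:`tsffit.topology` (0.0 for
  same-atom elements, 0.031 / 0.31 / 0.031 by bond separation). Elements
  touching frozen atoms are zero-weighted: atoms fixed in the reference
  calculation carry unphysical second derivatives.
* Eigenmode mode — one point per reference eigenvalue E_k, compared against
  (V^T H' V)_kk in the frozen reference eigenbasis V. The negative
  (reaction-mode) eigenvalue's weight is zeroed, which is what inverts the
  saddle into a minimum; trans/rot modes (|E| < 1 kcal/mol/A^2) are also
  zero-weighted as they carry no parameter information.

Geometric data points (bond lengths, angles, torsions of the FF-minimized
structure against the reference TS geometry) enter both modes, and tether
points pull selected parameters toward anchor values during early rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frcmod import FrcmodParameterSet
from .mm import Evaluator, minimize
from .qmref import NEGATIVE_MODE_THRESHOLD, ReferenceData
from .structures import MolecularSystem
from .topology import enumerate_internals, hessian_pair_weight, separation_matrix

__all__ = [
    "DataPoint",
    "ObjectiveWeights",
    "chi_squared",
    "assemble_cartesian_points",
    "eigenmode_points",
    "tether_points",
    "measure_internals",
    "CartesianObjective",
    "EigenmodeObjective",
    "residual_report",
]


@dataclass
class DataPoint:
    label: tuple
    reference: float
    calculated: float
    weight: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"negative weight on {self.label}")
        if not np.isfinite(self.reference):
            raise ValueError(f"non-finite reference on {self.label}")


@dataclass
class ObjectiveWeights:
    """Base weights per data-point kind (artifact defaults, configurable).

    The topological Hessian factors are the published scheme; these base
    weights set the relative scale of the geometric and Hessian blocks.
    """

    bond: float = 100.0    # per A
    angle: float = 2.0     # per degree
    torsion: float = 1.0   # per degree
    hessian: float = 1.0   # multiplies the topological factor


def chi_squared(points) -> float:
    """sum w_i^2 (x_i^0 - x_i)^2 over the data-point list."""
    return float(
        sum(p.weight**2 * (p.reference - p.calculated) ** 2 for p in points)
    )


def _wrap_deg(x):
    return (np.asarray(x) + 180.0) % 360.0 - 180.0


def measure_internals(coords: np.ndarray, table):
    """Bond lengths (A), angles and torsions (degrees) at given coordinates."""
    x = np.asarray(coords, dtype=float).reshape(-1, 3)
    if table.bonds:
        idx = np.array(table.bonds)
        bonds = np.linalg.norm(x[idx[:, 0]] - x[idx[:, 1]], axis=1)
    else:
        bonds = np.zeros(0)
    if table.angles:
        idx = np.array(table.angles)
        u = x[idx[:, 0]] - x[idx[:, 1]]
        w = x[idx[:, 2]] - x[idx[:, 1]]
        cos = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
        )
        angles = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    else:
        angles = np.zeros(0)
    if table.torsions:
        idx = np.array(table.torsions)
        phi, *_ = Evaluator._dihedral_geometry(x, idx)
        torsions = np.degrees(phi)
    else:
        torsions = np.zeros(0)
    return bonds, angles, torsions


def _hessian_weights(system: MolecularSystem, n3: int, base: float) -> np.ndarray:
    """Weight for every unique Hessian element (row-major upper triangle)."""
    sep = separation_matrix(system)
    frozen = system.frozen
    iu, ju = np.triu_indices(n3)
    ai, aj = iu // 3, ju // 3
    w = np.array(
        [hessian_pair_weight(int(s) if s >= 0 else "disconnected")
         for s in sep[ai, aj]]
    )
    w = base * w
    w[frozen[ai] | frozen[aj]] = 0.0
    return w


def _geometry_points(table, ref_vals, calc_vals, weights: ObjectiveWeights):
    points = []
    rb, ra, rt = ref_vals
    cb, ca, ct = calc_vals
    for k, pair in enumerate(table.bonds):
        points.append(DataPoint(("bond",) + tuple(pair), rb[k], cb[k], weights.bond))
    for k, tri in enumerate(table.angles):
        points.append(DataPoint(("angle",) + tuple(tri), ra[k], ca[k], weights.angle))
    for k, quad in enumerate(table.torsions):
        # wrap the residual into (-180, 180] so periodic images do not inflate chi^2
        calc = rt[k] - float(_wrap_deg(rt[k] - ct[k]))
        points.append(
            DataPoint(("torsion",) + tuple(quad), rt[k], calc, weights.torsion)
        )
    return points


def assemble_cartesian_points(
    ref: ReferenceData,
    system: MolecularSystem,
    params: FrcmodParameterSet,
    weights: ObjectiveWeights | None = None,
    *,
    evaluator: Evaluator | None = None,
    start: np.ndarray | None = None,
):
    """Data points of the Cartesian-Hessian objective.

    The FF side is evaluated at the FF-minimized geometry (frozen atoms held
    at the reference positions): the Hessian at the FF stationary point, and
    the geometric internals of that stationary point against the reference
    TS internals.
    """
    if ref.n_atoms != system.n_atoms:
        raise ValueError(
            f"reference has {ref.n_atoms} atoms, system has {system.n_atoms}"
        )
    weights = weights or ObjectiveWeights()
    ev = evaluator if evaluator is not None else Evaluator(system, params)
    start_coords = ref.coordinates if start is None else start
    res = minimize(system, params, start_coords, evaluator=ev)
    h_ff = ev.hessian(res.coordinates)

    n3 = 3 * system.n_atoms
    iu, ju = np.triu_indices(n3)
    w = _hessian_weights(system, n3, weights.hessian)
    points = [
        DataPoint(("hessian", int(i), int(j)), float(ref.hessian[i, j]),
                  float(h_ff[i, j]), float(wij))
        for i, j, wij in zip(iu, ju, w)
    ]
    table = enumerate_internals(system)
    ref_vals = measure_internals(ref.coordinates, table)
    calc_vals = measure_internals(res.coordinates, table)
    points.extend(_geometry_points(table, ref_vals, calc_vals, weights))
    return points


def eigenmode_points(ref: ReferenceData, ff_hessian: np.ndarray, base_weight=1.0):
    """One point per reference eigenvalue: E_k vs (V^T H' V)_kk.

    The reference eigenvectors V are preserved; the negative-mode point and
    trans/rot points get weight 0.
    """
    h = np.asarray(ff_hessian, dtype=float)
    if h.shape != ref.hessian.shape:
        raise ValueError(f"FF Hessian shape {h.shape} != {ref.hessian.shape}")
    v = ref.eigenvectors
    calc = np.einsum("ki,kl,li->i", v, h, v)  # diag(V^T H' V)
    tr = set(ref.trans_rot_indices)
    points = []
    for k, (e_ref, e_calc) in enumerate(zip(ref.eigenvalues, calc)):
        w = base_weight
        if k == ref.negative_mode_index or k in tr:
            w = 0.0
        elif abs(e_ref) < NEGATIVE_MODE_THRESHOLD:
            w = 0.0
        points.append(DataPoint(("eigenvalue", k), float(e_ref), float(e_calc), w))
    return points


def tether_points(handles, anchors=None, tether_weights=None):
    """One point per tethered parameter handle; weight 0 removes the tether."""
    points = []
    for idx, h in enumerate(handles):
        anchor = anchors[idx] if anchors is not None else h.tether_anchor
        w = tether_weights[idx] if tether_weights is not None else h.tether_weight
        if anchor is None:
            continue
        points.append(
            DataPoint(("tether",) + tuple(h.identifier), float(anchor),
                      float(h.value), float(w))
        )
    return points


class _ObjectiveBase:
    """Vectorized objective: fixed labels/references/weights, fast recompute
    of calculated values after a parameter refresh (warm-started minimizer)."""

    def __init__(self, ref, system, params, weights=None):
        if ref.n_atoms != system.n_atoms:
            raise ValueError(
                f"reference has {ref.n_atoms} atoms, system has {system.n_atoms}"
            )
        self.ref = ref
        self.system = system
        self.weights = weights or ObjectiveWeights()
        self.evaluator = Evaluator(system, params)
        self.table = enumerate_internals(system)
        self._ref_internals = measure_internals(ref.coordinates, self.table)
        self._anchor = ref.coordinates.copy()
        self.labels: list[tuple] = []
        self.ref_values: np.ndarray
        self.point_weights: np.ndarray

    def rebase(self, params) -> None:
        """Recompute the warm-start anchor from the reference TS geometry.

        Evaluations warm-start from a fixed anchor so that, between rebase
        calls, the objective is a pure function of the parameters (no
        path dependence across evaluations). Optimizers rebase at stage
        boundaries.
        """
        self.evaluator.refresh(params)
        res = minimize(
            self.system, params, self.ref.coordinates, evaluator=self.evaluator
        )
        self._anchor = res.coordinates

    def _minimized(self, params):
        self.evaluator.refresh(params)
        return minimize(
            self.system, params, self._anchor, evaluator=self.evaluator
        )

    def _geometry_calc(self, coords):
        cb, ca, ct = measure_internals(coords, self.table)
        rb, ra, rt = self._ref_internals
        ct = rt - _wrap_deg(rt - ct)
        return np.concatenate([cb, ca, ct])

    def _geometry_ref_w(self):
        rb, ra, rt = self._ref_internals
        refs = np.concatenate([rb, ra, rt])
        w = np.concatenate(
            [
                np.full(len(rb), self.weights.bond),
                np.full(len(ra), self.weights.angle),
                np.full(len(rt), self.weights.torsion),
            ]
        )
        labels = (
            [("bond",) + tuple(b) for b in self.table.bonds]
            + [("angle",) + tuple(a) for a in self.table.angles]
            + [("torsion",) + tuple(t) for t in self.table.torsions]
        )
        return labels, refs, w

    def calculated(self, params) -> np.ndarray:
        raise NotImplementedError

    def chi2(self, params) -> float:
        calc = self.calculated(params)
        r = self.ref_values - calc
        return float(np.sum((self.point_weights * r) ** 2))

    def points(self, params):
        calc = self.calculated(params)
        return [
            DataPoint(lbl, float(r), float(c), float(w))
            for lbl, r, c, w in zip(
                self.labels, self.ref_values, calc, self.point_weights
            )
        ]


class CartesianObjective(_ObjectiveBase):
    def __init__(self, ref, system, params, weights=None):
        super().__init__(ref, system, params, weights)
        n3 = 3 * system.n_atoms
        self._iu, self._ju = np.triu_indices(n3)
        hw = _hessian_weights(system, n3, self.weights.hessian)
        glabels, grefs, gw = self._geometry_ref_w()
        self.labels = [
            ("hessian", int(i), int(j)) for i, j in zip(self._iu, self._ju)
        ] + glabels
        self.ref_values = np.concatenate(
            [ref.hessian[self._iu, self._ju], grefs]
        )
        self.point_weights = np.concatenate([hw, gw])

    def calculated(self, params) -> np.ndarray:
        res = self._minimized(params)
        h = self.evaluator.hessian(res.coordinates)
        return np.concatenate(
            [h[self._iu, self._ju], self._geometry_calc(res.coordinates)]
        )


class EigenmodeObjective(_ObjectiveBase):
    def __init__(self, ref, system, params, weights=None):
        super().__init__(ref, system, params, weights)
        n3 = 3 * system.n_atoms
        ew = np.full(n3, self.weights.hessian)
        tr = set(ref.trans_rot_indices)
        for k in range(n3):
            if (
                k == ref.negative_mode_index
                or k in tr
                or abs(ref.eigenvalues[k]) < NEGATIVE_MODE_THRESHOLD
            ):
                ew[k] = 0.0
        glabels, grefs, gw = self._geometry_ref_w()
        self.labels = [("eigenvalue", k) for k in range(n3)] + glabels
        self.ref_values = np.concatenate([ref.eigenvalues, grefs])
        self.point_weights = np.concatenate([ew, gw])

    def calculated(self, params) -> np.ndarray:
        res = self._minimized(params)
        h = self.evaluator.hessian(res.coordinates)
        v = self.ref.eigenvectors
        diag = np.einsum("ki,kl,li->i", v, h, v)
        return np.concatenate([diag, self._geometry_calc(res.coordinates)])


def residual_report(points) -> str:
    """Plain-text table: label, reference, calculated, weight, w^2 r^2."""
    lines = ["label\treference\tcalculated\tweight\tweighted_sq_residual"]
    for p in points:
        wsq = p.weight**2 * (p.reference - p.calculated) ** 2
        lbl = ":".join(str(x) for x in p.label)
        lines.append(
            f"{lbl}\t{p.reference:.6f}\t{p.calculated:.6f}\t{p.weight:.4f}\t{wsq:.6e}"
        )
    return "\n".join(lines) + "\n"
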