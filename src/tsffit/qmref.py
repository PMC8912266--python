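"""Reference data for the fit: QM geometry, Cartesian Hessian, eigenmodes.

The training data for a transition-state force field is the electronic-
structure geometry and second-derivative (Hessian) matrix of the model
system at the TS. This module parses the Gaussian-style text log dialect
(geometry table + lower-triangular Cartesian force constants in
Hartree/Bohr^2), converts units to kcal/mol/A^2, and eigendecomposes the
symmetrized Hessian. A first-order saddle shows exactly one significant
negative eigenvalue — the reaction mode.

The Hessian is kept mass-unweighted throughout: the Amber-form potential's
second derivatives are mass-independent and frequencies are never needed by
the fit.

A plain-text archive format (``# tsffit reference archive v1``) stores the
same content losslessly so fixtures need no QM code.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HARTREE_TO_KCAL",
    "BOHR_TO_ANGSTROM",
    "HESSIAN_UNIT_FACTOR",
    "NEGATIVE_MODE_THRESHOLD",
    "ReferenceData",
    "QMLogError",
    "convert_hessian_units",
    "parse_qm_log",
    "read_archive",
    "write_archive",
    "load_reference",
]

HARTREE_TO_KCAL = 627.509474          # kcal/mol per Hartree
BOHR_TO_ANGSTROM = 0.529177210903     # A per Bohr
HESSIAN_UNIT_FACTOR = HARTREE_TO_KCAL / BOHR_TO_ANGSTROM**2

# Eigenvalues below -1 kcal/mol/A^2 count as genuinely negative curvature;
# smaller magnitudes are translational/rotational numerical noise.
NEGATIVE_MODE_THRESHOLD = 1.0

_SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
]
_NUMBERS = {s: z for z, s in enumerate(_SYMBOLS)}


class QMLogError(ValueError):
    pass


def convert_hessian_units(h):
    """Hartree/Bohr^2 -> kcal/mol/A^2 (multiplicative, invertible)."""
    return np.asarray(h, dtype=float) * HESSIAN_UNIT_FACTOR


def _n_trans_rot(coords: np.ndarray) -> int:
    """6 for a nonlinear system, 5 for a collinear one (3 for a single atom)."""
    n = coords.shape[0]
    if n == 1:
        return 3
    centered = coords - coords.mean(axis=0)
    # rank of the coordinate cloud: 1 => linear
    s = np.linalg.svd(centered, compute_uv=False)
    rank = int(np.sum(s > 1e-6 * max(1.0, s[0])))
    return 5 if rank <= 1 else 6


@dataclass
class ReferenceData:
    """QM TS geometry + Cartesian Hessian with cached eigendecomposition."""

    elements: list[str]
    coordinates: np.ndarray          # (N, 3) A
    hessian: np.ndarray              # (3N, 3N) kcal/mol/A^2, symmetric
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)   # columns
    negative_mode_index: int | None = field(init=False)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        h = np.asarray(self.hessian, dtype=float)
        n3 = 3 * self.n_atoms
        if h.shape != (n3, n3):
            raise QMLogError(f"Hessian shape {h.shape} != ({n3}, {n3})")
        scale = max(np.abs(h).max(), 1.0)
        if np.abs(h - h.T).max() > 1e-6 * scale:
            raise QMLogError("Hessian is not symmetric to 1e-6 relative tolerance")
        self.hessian = 0.5 * (h + h.T)
        self.eigenvalues, self.eigenvectors = np.linalg.eigh(self.hessian)
        self._classify_modes()

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_trans_rot(self) -> int:
        return _n_trans_rot(self.coordinates)

    def _classify_modes(self) -> None:
        # exclude the smallest-|eigenvalue| trans/rot block, then look for
        # significant negative curvature among the rest
        order = np.argsort(np.abs(self.eigenvalues))
        tr = set(order[: self.n_trans_rot].tolist())
        vib = [k for k in range(len(self.eigenvalues)) if k not in tr]
        neg = [k for k in vib if self.eigenvalues[k] < -NEGATIVE_MODE_THRESHOLD]
        if not neg:
            self.negative_mode_index = None
        else:
            if len(neg) > 1:
                warnings.warn(
                    f"{len(neg)} significant negative eigenvalues; proceeding on "
                    "the most negative (expected exactly one for a TS)",
                    stacklevel=3,
                )
            self.negative_mode_index = int(min(neg, key=lambda k: self.eigenvalues[k]))

    @property
    def trans_rot_indices(self) -> list[int]:
        order = np.argsort(np.abs(self.eigenvalues))
        return sorted(order[: self.n_trans_rot].tolist())


_GEOM_HEADERS = ("Standard orientation:", "Input orientation:")


def _parse_geometry_blocks(lines: list[str]):
    blocks = []
    i = 0
    while i < len(lines):
        if any(h in lines[i] for h in _GEOM_HEADERS):
            j = i + 5  # skip the table rule/header lines
            elements, coords = [], []
            while j < len(lines) and not lines[j].lstrip().startswith("---"):
                tok = lines[j].split()
                if len(tok) < 6:
                    break
                z = int(tok[1])
                elements.append(_SYMBOLS[z] if 0 < z < len(_SYMBOLS) else f"Z{z}")
                coords.append([float(tok[-3]), float(tok[-2]), float(tok[-1])])
                j += 1
            if elements:
                blocks.append((elements, np.array(coords)))
            i = j
        i += 1
    return blocks


def _parse_triangular_hessian(lines: list[str], start: int, dim: int) -> np.ndarray:
    """Gaussian-style lower-triangular block matrix with D-exponent floats."""
    h = np.zeros((dim, dim))
    i = start
    col_index: list[int] = []
    filled = 0
    while i < len(lines) and filled < dim * (dim + 1) // 2:
        tok = lines[i].split()
        if not tok:
            break
        if all(re.fullmatch(r"\d+", t) for t in tok):
            col_index = [int(t) - 1 for t in tok]
        else:
            row = int(tok[0]) - 1
            for c, t in zip(col_index, tok[1:]):
                h[row, c] = float(t.replace("D", "e").replace("d", "e"))
                filled += 1
        i += 1
    if filled != dim * (dim + 1) // 2:
        raise QMLogError(
            f"incomplete Hessian block: {filled} of {dim * (dim + 1) // 2} elements"
        )
    return h + np.tril(h, -1).T


def parse_qm_log(text: str) -> ReferenceData:
    """Parse a QM text log: final geometry (A) + Cartesian force constants.

    The force-constant block (``Force constants in Cartesian coordinates``)
    is lower-triangular in Hartree/Bohr^2; the last geometry and the last
    Hessian block in the file win. Output is symmetrized and converted to
    kcal/mol/A^2.
    """
    lines = text.splitlines()
    geoms = _parse_geometry_blocks(lines)
    if not geoms:
        raise QMLogError("no geometry block found in log")
    elements, coords = geoms[-1]
    dim = 3 * len(elements)

    starts = [
        i for i, line in enumerate(lines)
        if "Force constants in Cartesian coordinates" in line
    ]
    if not starts:
        raise QMLogError("no Cartesian force-constant block found in log")
    h_au = _parse_triangular_hessian(lines, starts[-1] + 1, dim)
    h = convert_hessian_units(0.5 * (h_au + h_au.T))
    return ReferenceData(elements=elements, coordinates=coords, hessian=h)


ARCHIVE_MAGIC = "# tsffit reference archive v1"


def write_archive(ref: ReferenceData) -> str:
    """Lossless plain-text serialization (coordinates + upper-triangular H)."""
    n = ref.n_atoms
    buf = io.StringIO()
    buf.write(ARCHIVE_MAGIC + "\n")
    buf.write(f"natoms {n}\n")
    buf.write("elements " + " ".join(ref.elements) + "\n")
    buf.write("coordinates\n")
    for xyz in ref.coordinates:
        buf.write(f"{float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}\n")
    buf.write("hessian_upper\n")
    for i in range(3 * n):
        buf.write(" ".join(repr(float(v)) for v in ref.hessian[i, i:]) + "\n")
    return buf.getvalue()


def read_archive(text: str) -> ReferenceData:
    lines = text.splitlines()
    if not lines or lines[0].strip() != ARCHIVE_MAGIC:
        raise QMLogError("not a tsffit reference archive")
    n = int(lines[1].split()[1])
    elements = lines[2].split()[1:]
    if len(elements) != n:
        raise QMLogError("element count mismatch in archive")
    if lines[3].strip() != "coordinates":
        raise QMLogError("malformed archive: expected coordinates block")
    coords = np.array(
        [[float(v) for v in lines[4 + i].split()] for i in range(n)]
    )
    if lines[4 + n].strip() != "hessian_upper":
        raise QMLogError("malformed archive: expected hessian_upper block")
    dim = 3 * n
    h = np.zeros((dim, dim))
    for i in range(dim):
        row = [float(v) for v in lines[5 + n + i].split()]
        h[i, i:] = row
    h = h + np.triu(h, 1).T
    return ReferenceData(elements=elements, coordinates=coords, hessian=h)


def load_reference(text: str) -> ReferenceData:
    """Dispatch on content: archive format or QM log dialect."""
    if text.lstrip().startswith(ARCHIVE_MAGIC):
        return read_archive(text)
    return parse_qm_log(text)
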