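"""Molecular system container and structure-file IO.

A :class:`MolecularSystem` holds what the fit needs to know about the model
system: coordinates, Amber atom types, fixed partial charges, the bond graph
and per-atom frozen flags. Structures arrive either as Tripos mol2 (types,
charges and connectivity self-contained) or as PDB coordinates plus a
plain-text charge/connectivity library, mirroring the split used for
QM/MM-derived enzyme models. Charges are fixed inputs; they are never refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "MolecularSystem",
    "StructureError",
    "parse_structure",
    "parse_charge_library",
    "parse_frozen_list",
    "write_mol2",
    "write_pdb",
    "write_charge_library",
]


class StructureError(ValueError):
    pass


@dataclass
class Atom:
    index: int
    name: str
    atom_type: str
    element: str
    charge: float = 0.0
    residue: str = "MOL"


@dataclass
class MolecularSystem:
    atoms: list[Atom]
    coordinates: np.ndarray            # (N, 3) Angstrom
    bonds: list[tuple[int, int]] = field(default_factory=list)
    frozen: np.ndarray | None = None   # (N,) bool

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if self.frozen is None:
            self.frozen = np.zeros(len(self.atoms), dtype=bool)
        self.frozen = np.asarray(self.frozen, dtype=bool)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def atom_types(self) -> list[str]:
        return [a.atom_type for a in self.atoms]

    def validate(self) -> None:
        n = len(self.atoms)
        if self.coordinates.shape != (n, 3):
            raise StructureError(
                f"coordinate array shape {self.coordinates.shape} != ({n}, 3)"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError("non-finite coordinates")
        seen = set()
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(f"bond ({i}, {j}) out of range")
            if i == j:
                raise StructureError(f"self-bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise StructureError(f"duplicate bond {key}")
            seen.add(key)
        total = float(np.sum(self.charges))
        if abs(total - round(total)) > 1e-3:
            raise StructureError(
                f"total charge {total:.6f} is not integral to 1e-3 e"
            )

    def index_of(self, name: str) -> int:
        matches = [a.index for a in self.atoms if a.name == name]
        if len(matches) != 1:
            raise StructureError(
                f"atom name {name!r} resolves to {len(matches)} atoms"
            )
        return matches[0]


_ELEMENTS = {
    "H", "C", "N", "O", "F", "P", "S", "CL", "BR", "I", "NA", "K", "MG", "ZN", "FE",
}


def _element_from_name(name: str) -> str:
    """PDB-style element guess: try two-letter then one-letter symbol."""
    stripped = name.strip().lstrip("0123456789")
    two = stripped[:2].upper()
    if two in _ELEMENTS and len(stripped) >= 2:
        return two.capitalize()
    one = stripped[:1].upper()
    if one in _ELEMENTS:
        return one
    return stripped[:1].upper() or "X"


def parse_charge_library(text: str):
    """Parse the plain-text charge/connectivity library.

    Grammar: an ``!atoms`` block of ``name type charge`` lines and an optional
    ``!bonds`` block of ``name1 name2`` lines; ``#`` starts a comment.
    Returns ``(records, bond_name_pairs)`` with records name -> (type, charge).
    """
    records: dict[str, tuple[str, float]] = {}
    bond_pairs: list[tuple[str, str]] = []
    mode = "atoms"
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("!"):
            word = line[1:].strip().lower()
            if word not in ("atoms", "bonds"):
                raise StructureError(f"library line {lineno}: unknown block {line!r}")
            mode = word
            continue
        tok = line.split()
        if mode == "atoms":
            if len(tok) != 3:
                raise StructureError(
                    f"library line {lineno}: expected 'name type charge'"
                )
            if tok[0] in records:
                raise StructureError(f"library line {lineno}: duplicate atom {tok[0]!r}")
            records[tok[0]] = (tok[1], float(tok[2]))
        else:
            if len(tok) != 2:
                raise StructureError(f"library line {lineno}: expected 'name1 name2'")
            bond_pairs.append((tok[0], tok[1]))
    return records, bond_pairs


def parse_frozen_list(text: str) -> list[str]:
    """One atom name per line; blank lines and ``#`` comments ignored."""
    names = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            names.append(line)
    return names


def _parse_mol2(text: str):
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    bonds: list[tuple[int, int]] = []
    section = None
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[len("@<TRIPOS>"):].upper()
            continue
        if not line or section is None:
            continue
        if section == "ATOM":
            tok = line.split()
            if len(tok) < 6:
                raise StructureError(f"malformed mol2 ATOM line: {raw!r}")
            name, x, y, z, atype = tok[1], tok[2], tok[3], tok[4], tok[5]
            residue = tok[7] if len(tok) > 7 else "MOL"
            charge = float(tok[8]) if len(tok) > 8 else 0.0
            atoms.append(
                Atom(
                    index=len(atoms),
                    name=name,
                    atom_type=atype,
                    element=_element_from_name(name),
                    charge=charge,
                    residue=residue,
                )
            )
            coords.append([float(x), float(y), float(z)])
        elif section == "BOND":
            tok = line.split()
            if len(tok) < 3:
                raise StructureError(f"malformed mol2 BOND line: {raw!r}")
            bonds.append((int(tok[1]) - 1, int(tok[2]) - 1))
    if not atoms:
        raise StructureError("mol2 content contains no atoms")
    return atoms, np.array(coords), bonds


def _parse_pdb(text: str):
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    for raw in text.splitlines():
        if not raw.startswith(("ATOM", "HETATM")):
            continue
        name = raw[12:16].strip()
        residue = raw[17:20].strip() or "MOL"
        x, y, z = float(raw[30:38]), float(raw[38:46]), float(raw[46:54])
        element = raw[76:78].strip() if len(raw) >= 78 else ""
        atoms.append(
            Atom(
                index=len(atoms),
                name=name,
                atom_type="",  # assigned from the charge library
                element=element.capitalize() or _element_from_name(name),
                residue=residue,
            )
        )
        coords.append([x, y, z])
    if not atoms:
        raise StructureError("PDB content contains no ATOM/HETATM records")
    return atoms, np.array(coords), []


def parse_structure(
    structure_text: str,
    charges_text: str | None = None,
    frozen_names: list[str] | str | None = None,
) -> MolecularSystem:
    """Assemble a :class:`MolecularSystem` from structure + library + frozen list.

    mol2 input is self-contained (types, charges, bonds); a charge library, if
    given, overrides charges/types and may add bonds. PDB input requires the
    library for types, charges and connectivity. Matching is by atom name,
    case-sensitive, whitespace-stripped — ordering between the files is free.
    """
    if "@<TRIPOS>" in structure_text:
        atoms, coords, bonds = _parse_mol2(structure_text)
    else:
        atoms, coords, bonds = _parse_pdb(structure_text)

    names = [a.name for a in atoms]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise StructureError(f"duplicate atom names in structure: {dupes}")
    by_name = {a.name: a for a in atoms}

    if charges_text is not None:
        records, bond_pairs = parse_charge_library(charges_text)
        unknown = sorted(set(records) - set(by_name))
        if unknown:
            raise StructureError(f"library names absent from structure: {unknown}")
        for name, (atype, charge) in records.items():
            by_name[name].atom_type = atype
            by_name[name].charge = charge
        existing = {(min(b), max(b)) for b in bonds}
        for n1, n2 in bond_pairs:
            for n in (n1, n2):
                if n not in by_name:
                    raise StructureError(f"bond references unknown atom {n!r}")
            pair = (by_name[n1].index, by_name[n2].index)
            key = (min(pair), max(pair))
            if key not in existing:
                bonds.append(pair)
                existing.add(key)

    missing_types = [a.name for a in atoms if not a.atom_type]
    if missing_types:
        raise StructureError(
            f"atoms without an atom type (no library entry): {missing_types}"
        )

    frozen = np.zeros(len(atoms), dtype=bool)
    if frozen_names is not None:
        if isinstance(frozen_names, str):
            frozen_names = parse_frozen_list(frozen_names)
        for name in frozen_names:
            name = name.strip()
            if name not in by_name:
                raise StructureError(f"frozen list names unknown atom {name!r}")
            frozen[by_name[name].index] = True

    return MolecularSystem(atoms=atoms, coordinates=coords, bonds=bonds, frozen=frozen)


def write_mol2(system: MolecularSystem, title: str = "MOL") -> str:
    n, nb = system.n_atoms, len(system.bonds)
    out = [
        "@<TRIPOS>MOLECULE",
        title,
        f"{n:5d} {nb:5d}     1",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for a, xyz in zip(system.atoms, system.coordinates):
        out.append(
            f"{a.index + 1:7d} {a.name:<8s} {xyz[0]:10.4f} {xyz[1]:10.4f}"
            f" {xyz[2]:10.4f} {a.atom_type:<6s} 1 {a.residue:<8s} {a.charge:10.6f}"
        )
    out.append("@<TRIPOS>BOND")
    for k, (i, j) in enumerate(system.bonds, start=1):
        out.append(f"{k:6d} {i + 1:5d} {j + 1:5d} 1")
    return "\n".join(out) + "\n"


def write_pdb(system: MolecularSystem) -> str:
    out = []
    for a, xyz in zip(system.atoms, system.coordinates):
        out.append(
            f"HETATM{a.index + 1:5d} {a.name:<4s}{a.residue:<4s} A   1    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {a.element:>2s}"
        )
    out.append("END")
    return "\n".join(out) + "\n"


def write_charge_library(system: MolecularSystem) -> str:
    out = ["!atoms"]
    for a in system.atoms:
        out.append(f"{a.name} {a.atom_type} {a.charge:.6f}")
    out.append("!bonds")
    names = [a.name for a in system.atoms]
    for i, j in system.bonds:
        out.append(f"{names[i]} {names[j]}")
    return "\n".join(out) + "\n"
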