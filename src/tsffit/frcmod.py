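"""Amber frcmod (force-field modification) file reading and writing.

A frcmod file carries the bonded and nonbonded parameters that are the
degrees of freedom of a transition-state force-field fit: MASS, BOND,
ANGLE, DIHE, IMPROPER and NONBON sections keyed by atom type. Both
blank-line-terminated and header-terminated sections are accepted.

Multi-term dihedrals follow the Amber continuation convention: every term
of a Fourier series except the last is written with a negative periodicity;
on parse the series is folded into one list of terms, and the writer
restores the convention.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "DihedralTerm",
    "BondTerm",
    "AngleTerm",
    "NonbondedTerm",
    "FrcmodParameterSet",
    "FrcmodError",
    "parse_frcmod",
    "write_frcmod",
]

_SECTION_ALIASES = {
    "MASS": "MASS",
    "BOND": "BOND",
    "ANGL": "ANGLE",
    "ANGLE": "ANGLE",
    "DIHE": "DIHE",
    "DIHEDRAL": "DIHE",
    "IMPROPER": "IMPROPER",
    "IMPR": "IMPROPER",
    "NONBON": "NONBON",
    "NONB": "NONBON",
}


class FrcmodError(ValueError):
    """Raised for malformed frcmod content; message names the offending line."""


@dataclass
class BondTerm:
    k: float      # kcal/mol/A^2
    r0: float     # A


@dataclass
class AngleTerm:
    k: float      # kcal/mol/rad^2
    theta0: float  # degrees


@dataclass
class DihedralTerm:
    divider: int
    barrier: float       # kcal/mol
    phase: float         # degrees
    periodicity: int     # positive after parsing


@dataclass
class NonbondedTerm:
    rmin_half: float  # A
    epsilon: float    # kcal/mol


@dataclass
class FrcmodParameterSet:
    """All parameters of an Amber-dialect frcmod file, keyed by atom type."""

    title: str = "parameters"
    masses: dict[str, float] = field(default_factory=dict)
    bond_terms: dict[tuple[str, str], BondTerm] = field(default_factory=dict)
    angle_terms: dict[tuple[str, str, str], AngleTerm] = field(default_factory=dict)
    dihedral_terms: dict[tuple[str, str, str, str], list[DihedralTerm]] = field(
        default_factory=dict
    )
    improper_terms: dict[tuple[str, str, str, str], list[DihedralTerm]] = field(
        default_factory=dict
    )
    nonbonded: dict[str, NonbondedTerm] = field(default_factory=dict)

    def copy(self) -> "FrcmodParameterSet":
        import copy as _copy

        return _copy.deepcopy(self)

    def validate(self) -> None:
        for key, b in self.bond_terms.items():
            if b.k < 0:
                raise FrcmodError(f"negative bond force constant for {key}")
            if b.r0 <= 0:
                raise FrcmodError(f"non-positive equilibrium length for {key}")
        for key, a in self.angle_terms.items():
            if a.k < 0:
                raise FrcmodError(f"negative angle force constant for {key}")
            if not 0.0 < a.theta0 <= 180.0:
                raise FrcmodError(f"equilibrium angle out of (0, 180] for {key}")
        for table in (self.dihedral_terms, self.improper_terms):
            for key, terms in table.items():
                for t in terms:
                    if t.periodicity == 0 or t.periodicity != int(t.periodicity):
                        raise FrcmodError(f"zero periodicity for {key}")
                    if not math.isfinite(t.barrier):
                        raise FrcmodError(f"non-finite barrier for {key}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrcmodParameterSet):
            return NotImplemented
        return (
            self.masses == other.masses
            and self.bond_terms == other.bond_terms
            and self.angle_terms == other.angle_terms
            and self.dihedral_terms == other.dihedral_terms
            and self.improper_terms == other.improper_terms
            and self.nonbonded == other.nonbonded
        )


def _split_key(field_text: str, natoms: int, lineno: int) -> tuple[str, ...]:
    parts = [p.strip() for p in field_text.split("-")]
    if len(parts) != natoms or any(not p for p in parts):
        raise FrcmodError(
            f"line {lineno}: expected {natoms}-atom type key, got {field_text!r}"
        )
    return tuple(parts)


_NUM = re.compile(r"[-+]?\d*\.?\d+(?:[eEdD][-+]?\d+)?")


def _parse_line(line: str, natoms: int, nfields: int, lineno: int):
    """Split a parameter line into the type key and exactly-nfields numbers.

    The key occupies the fixed-width head of the line (Amber pads one-char
    types: ``c -o ``); a free-format ``ct-c3 310.0 1.526`` layout is accepted
    as a fallback.
    """
    width = 3 * natoms - 1
    head, tail = line[:width], line[width:]
    if head.count("-") == natoms - 1 and tail[:1] in ("", " ", "\t"):
        key = _split_key(head, natoms, lineno)
        rest = tail
    else:
        # free-format: key is the first whitespace-delimited token
        tok = line.split(None, 1)
        if len(tok) < 2 or tok[0].count("-") != natoms - 1:
            raise FrcmodError(f"line {lineno}: cannot parse type key in {line!r}")
        key = _split_key(tok[0], natoms, lineno)
        rest = tok[1]
    nums = _NUM.findall(rest)
    if len(nums) < nfields:
        raise FrcmodError(
            f"line {lineno}: expected {nfields} numeric fields, found {len(nums)}"
        )
    try:
        vals = [float(v.replace("D", "e").replace("d", "e")) for v in nums[:nfields]]
    except ValueError as exc:  # pragma: no cover - regex guards this
        raise FrcmodError(f"line {lineno}: bad numeric field in {line!r}") from exc
    return key, vals


def parse_frcmod(text: str) -> FrcmodParameterSet:
    """Parse frcmod content into a :class:`FrcmodParameterSet`.

    Raises :class:`FrcmodError` naming the line for malformed numeric fields
    or unrecognized section headers.
    """
    params = FrcmodParameterSet()
    lines = text.splitlines()
    section: str | None = None
    title_seen = False
    # continuation state for multi-term dihedrals/impropers
    open_key: tuple[str, ...] | None = None
    open_table: dict | None = None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        stripped = line.strip()
        if not stripped:
            # blank line ends the current section (both conventions accepted)
            section = None
            open_key = None
            continue
        upper = stripped.upper()
        if section is None:
            if upper in _SECTION_ALIASES:
                section = _SECTION_ALIASES[upper]
                continue
            if not title_seen:
                params.title = stripped
                title_seen = True
                continue
            raise FrcmodError(f"line {lineno}: unknown section header {stripped!r}")
        if upper in _SECTION_ALIASES:
            section = _SECTION_ALIASES[upper]
            open_key = None
            continue

        if section == "MASS":
            tok = stripped.split()
            if len(tok) < 2:
                raise FrcmodError(f"line {lineno}: malformed MASS line {line!r}")
            try:
                params.masses[tok[0]] = float(tok[1])
            except ValueError as exc:
                raise FrcmodError(f"line {lineno}: bad mass {tok[1]!r}") from exc
        elif section == "BOND":
            key, (k, r0) = _parse_line(line, 2, 2, lineno)
            params.bond_terms[key] = BondTerm(k=k, r0=r0)
        elif section == "ANGLE":
            key, (k, th0) = _parse_line(line, 3, 2, lineno)
            params.angle_terms[key] = AngleTerm(k=k, theta0=th0)
        elif section in ("DIHE", "IMPROPER"):
            table = params.dihedral_terms if section == "DIHE" else params.improper_terms
            if section == "DIHE":
                key, (div, pk, phase, pn) = _parse_line(line, 4, 4, lineno)
                term = DihedralTerm(
                    divider=int(round(div)),
                    barrier=pk,
                    phase=phase,
                    periodicity=abs(int(round(pn))),
                )
            else:
                key, (pk, phase, pn) = _parse_line(line, 4, 3, lineno)
                term = DihedralTerm(
                    divider=1, barrier=pk, phase=phase, periodicity=abs(int(round(pn)))
                )
                div, pn = 1, pn
            if open_key == key and open_table is table:
                table[key].append(term)
            else:
                table.setdefault(key, [])
                table[key].append(term)
            # negative periodicity: further terms for the same dihedral follow
            if int(round(pn)) < 0:
                open_key, open_table = key, table
            else:
                open_key, open_table = None, None
        elif section == "NONBON":
            tok = stripped.split()
            if len(tok) < 3:
                raise FrcmodError(f"line {lineno}: malformed NONBON line {line!r}")
            try:
                params.nonbonded[tok[0]] = NonbondedTerm(
                    rmin_half=float(tok[1]), epsilon=float(tok[2])
                )
            except ValueError as exc:
                raise FrcmodError(f"line {lineno}: bad NONBON field in {line!r}") from exc
        else:  # pragma: no cover - section set is closed
            raise FrcmodError(f"line {lineno}: unknown section {section!r}")

    params.validate()
    return params


def _fmt_key(key: tuple[str, ...]) -> str:
    return "-".join(f"{t:<2s}" for t in key).rstrip()


def write_frcmod(params: FrcmodParameterSet) -> str:
    """Serialize a parameter set to frcmod text.

    Lengths are written with 4 decimals, force constants and barriers with 2,
    angles and phases with 3; the output re-parses to an identical set once
    values are representable at that precision.
    """
    params.validate()
    out: list[str] = [params.title, "MASS"]
    for atype, mass in params.masses.items():
        out.append(f"{atype:<2s}  {mass:.3f}")
    out.append("")
    out.append("BOND")
    for key, b in params.bond_terms.items():
        out.append(f"{_fmt_key(key):<5s}  {b.k:10.2f}  {b.r0:8.4f}")
    out.append("")
    out.append("ANGLE")
    for key, a in params.angle_terms.items():
        out.append(f"{_fmt_key(key):<8s}  {a.k:10.2f}  {a.theta0:9.3f}")
    out.append("")
    out.append("DIHE")
    for key, terms in params.dihedral_terms.items():
        for i, t in enumerate(terms):
            pn = t.periodicity if i == len(terms) - 1 else -t.periodicity
            out.append(
                f"{_fmt_key(key):<11s}  {t.divider:2d}  {t.barrier:10.2f}"
                f"  {t.phase:9.3f}  {pn:4d}"
            )
    out.append("")
    out.append("IMPROPER")
    for key, terms in params.improper_terms.items():
        for i, t in enumerate(terms):
            pn = t.periodicity if i == len(terms) - 1 else -t.periodicity
            out.append(
                f"{_fmt_key(key):<11s}  {t.barrier:10.2f}  {t.phase:9.3f}  {pn:4d}"
            )
    out.append("")
    out.append("NONBON")
    for atype, nb in params.nonbonded.items():
        out.append(f"  {atype:<2s}  {nb.rmin_half:8.4f}  {nb.epsilon:10.4f}")
    out.append("")
    return "\n".join(out) + "\n"
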