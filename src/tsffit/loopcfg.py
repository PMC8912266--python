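"""Loop configuration: the staged fitting program and its input paths.

The file format is line-oriented, one directive per line:

    FFLD <frcmod path>            # parameters to fit
    RDAT <reference path>         # QM log or reference archive
    CDAT structure <path>         # mol2 or PDB
    CDAT charges <path>           # charge/connectivity library (optional for mol2)
    CDAT frozen <path>            # frozen-atom list (optional)
    MODE cartesian|eigenmode
    SEED <int>
    LOOP <convergence fraction>   # opens a round; closed by END
    STAGE <kind,kind,...> [opt=simplex|newton|auto] [max_iter=N]
          [tether=w1,w2,...] [zero_dihedrals] [seed_dihedrals]
    END

Each LOOP block is one macro-round: its stages are cycled until the penalty
function changes by less than the stated fraction between successive cycles
(10% for the first round, 1% for refinement, following the published
workflow). ``#`` starts a comment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PARAMETER_KINDS",
    "StageSpec",
    "RoundSpec",
    "LoopConfig",
    "LoopConfigError",
    "parse_loop_config",
    "write_loop_config",
    "default_stage_program",
]

PARAMETER_KINDS = ("bond_k", "bond_r0", "angle_k", "angle_theta0", "dihedral_V")


class LoopConfigError(ValueError):
    pass


@dataclass
class StageSpec:
    kinds: list[str]
    optimizer: str = "auto"          # auto: simplex for <= 40 parameters
    max_iter: int | None = None
    tether: list[float] = field(default_factory=list)  # weight per macro-cycle
    zero_dihedrals: bool = False     # hold all dihedral barriers at zero (once)
    seed_dihedrals: bool = False     # restore input barriers, clamped to floor

    def __post_init__(self) -> None:
        if not self.kinds:
            raise LoopConfigError("stage with empty parameter selection")
        bad = [k for k in self.kinds if k not in PARAMETER_KINDS]
        if bad:
            raise LoopConfigError(f"unknown parameter kinds {bad}")
        if self.optimizer not in ("auto", "simplex", "newton"):
            raise LoopConfigError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class RoundSpec:
    convergence: float
    stages: list[StageSpec]
    max_cycles: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.convergence <= 1.0:
            raise LoopConfigError(
                f"convergence fraction {self.convergence} outside (0, 1]"
            )


@dataclass
class LoopConfig:
    rounds: list[RoundSpec]
    mode: str = "cartesian"
    seed: int = 0
    ffld: str | None = None
    rdat: str | None = None
    structure: str | None = None
    charges: str | None = None
    frozen: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cartesian", "eigenmode"):
            raise LoopConfigError(f"unknown mode {self.mode!r}")
        if not self.rounds:
            raise LoopConfigError("no LOOP rounds defined")


def default_stage_program() -> list[RoundSpec]:
    """The canonical staged program: force constants first (dihedral barriers
    held at zero), then bond lengths, then angles under a decreasing tether,
    then dihedral barriers seeded from the input (GAFF-derived) values; one
    10% round followed by a 1% Newton-refined round."""
    round1 = RoundSpec(
        convergence=0.10,
        max_cycles=2,
        stages=[
            # barriers are zeroed only while the force constants are being
            # determined (a light touch: later cycles re-balance); they are
            # restored from the input (GAFF-derived) values before any
            # equilibrium geometry is refined — fitting r0/theta0 against
            # freely rotating torsions chases meaningless geometry
            StageSpec(kinds=["bond_k", "angle_k"], optimizer="newton",
                      zero_dihedrals=True, max_iter=2),
            StageSpec(kinds=["bond_r0"], optimizer="newton",
                      seed_dihedrals=True, max_iter=3),
            StageSpec(kinds=["angle_theta0"], optimizer="newton",
                      tether=[10.0, 3.0, 0.0], max_iter=3),
            StageSpec(kinds=["dihedral_V"], optimizer="newton", max_iter=3),
        ],
    )
    round2 = RoundSpec(
        convergence=0.01,
        max_cycles=3,
        stages=[
            StageSpec(
                kinds=["bond_k", "bond_r0", "angle_k", "angle_theta0", "dihedral_V"],
                optimizer="newton",
                max_iter=20,
            ),
        ],
    )
    return [round1, round2]


def parse_loop_config(text: str) -> LoopConfig:
    rounds: list[RoundSpec] = []
    current: RoundSpec | None = None
    kw: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        word = tok[0].upper()
        try:
            if word == "FFLD":
                kw["ffld"] = tok[1]
            elif word == "RDAT":
                kw["rdat"] = tok[1]
            elif word == "CDAT":
                if len(tok) < 3 or tok[1] not in ("structure", "charges", "frozen"):
                    raise LoopConfigError(
                        f"line {lineno}: CDAT expects structure|charges|frozen <path>"
                    )
                kw[tok[1]] = tok[2]
            elif word == "MODE":
                kw["mode"] = tok[1]
            elif word == "SEED":
                kw["seed"] = int(tok[1])
            elif word == "LOOP":
                if current is not None:
                    raise LoopConfigError(f"line {lineno}: nested LOOP")
                current = RoundSpec(convergence=float(tok[1]), stages=[])
            elif word == "END":
                if current is None:
                    raise LoopConfigError(f"line {lineno}: END without LOOP")
                if not current.stages:
                    raise LoopConfigError(f"line {lineno}: LOOP with no stages")
                rounds.append(current)
                current = None
            elif word == "STAGE":
                if current is None:
                    raise LoopConfigError(f"line {lineno}: STAGE outside LOOP")
                kinds = tok[1].split(",")
                opts: dict = {}
                for t in tok[2:]:
                    if t == "zero_dihedrals":
                        opts["zero_dihedrals"] = True
                    elif t == "seed_dihedrals":
                        opts["seed_dihedrals"] = True
                    elif t.startswith("opt="):
                        opts["optimizer"] = t[4:]
                    elif t.startswith("max_iter="):
                        opts["max_iter"] = int(t[9:])
                    elif t.startswith("tether="):
                        opts["tether"] = [float(v) for v in t[7:].split(",")]
                    else:
                        raise LoopConfigError(f"line {lineno}: unknown option {t!r}")
                current.stages.append(StageSpec(kinds=kinds, **opts))
            else:
                raise LoopConfigError(f"line {lineno}: unknown directive {word!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, LoopConfigError):
                raise
            raise LoopConfigError(f"line {lineno}: malformed directive {line!r}") from exc
    if current is not None:
        raise LoopConfigError("unterminated LOOP block")
    return LoopConfig(rounds=rounds, **kw)


def write_loop_config(config: LoopConfig) -> str:
    out = []
    if config.ffld:
        out.append(f"FFLD {config.ffld}")
    if config.rdat:
        out.append(f"RDAT {config.rdat}")
    for fld in ("structure", "charges", "frozen"):
        val = getattr(config, fld)
        if val:
            out.append(f"CDAT {fld} {val}")
    out.append(f"MODE {config.mode}")
    out.append(f"SEED {config.seed}")
    for rnd in config.rounds:
        out.append(f"LOOP {rnd.convergence:g}")
        for st in rnd.stages:
            parts = ["STAGE", ",".join(st.kinds)]
            if st.optimizer != "auto":
                parts.append(f"opt={st.optimizer}")
            if st.max_iter is not None:
                parts.append(f"max_iter={st.max_iter}")
            if st.tether:
                parts.append("tether=" + ",".join(f"{w:g}" for w in st.tether))
            if st.zero_dihedrals:
                parts.append("zero_dihedrals")
            if st.seed_dihedrals:
                parts.append("seed_dihedrals")
            out.append(" ".join(parts))
        out.append("END")
    return "\n".join(out) + "\n"
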