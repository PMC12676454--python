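"""Built-in example model and a seeded random-model generator.

The EGFR early-signaling example encodes ligand binding, per-site
dephosphorylation, dimerization via ligand-bound receptors, and per-site
transphosphorylation within the dimer.  This exact formulation is pinned
because diagram content depends on how rules are written: monomer
modifications use single-receptor patterns, dimer modifications use explicit
dimer bonds, and dimerization requires ligand occupancy only via ``!+``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from mpdiag.errors import ModelValidationError
from mpdiag.bngl.model import Model
from mpdiag.bngl.parser import parse_model

__all__ = ["EGFR_BNGL", "egfr_model", "GeneratorConfig", "random_model"]

EGFR_BNGL = """\
# EGFR early signaling example: ligand binding, dimerization,
# transphosphorylation and dephosphorylation over two tyrosines.
begin parameters
  kon 1
  kdim 1
  kp 1
  kd 1
end parameters
begin molecule types
  EGF(site)
  EGFR(ecd,tmd,Y1~U~P,Y2~U~P)
end molecule types
begin seed species
  EGF(site) 1
  EGFR(ecd,tmd,Y1~U,Y2~U) 1
  EGFR(ecd,tmd,Y1~U,Y2~P) 1
  EGFR(ecd,tmd,Y1~P,Y2~U) 1
  EGFR(ecd,tmd,Y1~P,Y2~P) 1
end seed species
begin reaction rules
  R1: EGF(site) + EGFR(ecd,tmd) -> EGF(site!1).EGFR(ecd!1,tmd) kon
  R2: EGFR(Y1~P) -> EGFR(Y1~U) kd
  R3: EGFR(Y2~P) -> EGFR(Y2~U) kd
  R4: EGFR(ecd!+,tmd) + EGFR(ecd!+,tmd) -> EGFR(ecd!+,tmd!1).EGFR(ecd!+,tmd!1) kdim
  R5: EGFR(tmd!1).EGFR(tmd!1,Y1~U) -> EGFR(tmd!1).EGFR(tmd!1,Y1~P) kp
  R6: EGFR(tmd!1).EGFR(tmd!1,Y2~U) -> EGFR(tmd!1).EGFR(tmd!1,Y2~P) kp
end reaction rules
"""


def egfr_model() -> Model:
    """The six-rule EGFR example (two molecule types, five seed species)."""
    return parse_model(EGFR_BNGL, name="egfr")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for :func:`random_model`; identical config + seed gives an identical model."""

    seed: int = 0
    n_molecule_types: int = 3
    components_per_type: tuple[int, int] = (1, 3)
    states_per_component: tuple[int, int] = (0, 2)
    n_rules: int = 6
    max_pattern_size: int = 2
    p_wildcard: float = 0.25
    p_context: float = 0.5
    p_reversible: float = 0.2

    def validate(self) -> None:
        if self.n_molecule_types < 1 and self.n_rules > 0:
            raise ModelValidationError("rules require at least one molecule type")
        if self.max_pattern_size < 1 and self.n_rules > 0:
            raise ModelValidationError("max_pattern_size must be >= 1 when rules are generated")
        for p in (self.p_wildcard, self.p_context, self.p_reversible):
            if not 0.0 <= p <= 1.0:
                raise ModelValidationError(f"probability {p} outside [0, 1]")
        for lo, hi in (self.components_per_type, self.states_per_component):
            if lo < 0 or hi < lo:
                raise ModelValidationError(f"bad range ({lo}, {hi})")
        if self.components_per_type[1] < 1 and self.n_rules > 0:
            raise ModelValidationError("rules need at least one component per type")


def random_model(config: GeneratorConfig) -> Model:
    """Generate a syntactically valid model; deterministic per (config, seed)."""
    config.validate()
    rng = random.Random(config.seed)
    lines: list[str] = []

    lines.append("begin parameters")
    for i in range(1, config.n_rules * 2 + 1):
        lines.append(f"  k{i} 1")
    lines.append("end parameters")

    lines.append("begin molecule types")
    types: list[tuple[str, list[tuple[str, list[str]]]]] = []
    for ti in range(config.n_molecule_types):
        name = f"M{ti + 1}"
        lo, hi = config.components_per_type
        n_comp = max(rng.randint(lo, hi), 1)
        comps: list[tuple[str, list[str]]] = []
        for ci in range(n_comp):
            slo, shi = config.states_per_component
            n_states = rng.randint(slo, shi)
            if n_states == 1:
                n_states = 2  # a single allowed state is pointless
            states = [f"s{j}" for j in range(n_states)]
            comps.append((f"x{ci}", states))
        types.append((name, comps))
        decl = ",".join(c + "".join(f"~{s}" for s in sts) for c, sts in comps)
        lines.append(f"  {name}({decl})")
    lines.append("end molecule types")

    def context_suffixes(tname: str, skip: str) -> list[str]:
        """Random constraints on components other than ``skip`` (same both sides)."""
        comps = dict(next(c for n, c in types if n == tname))
        out = []
        for cname, states in comps.items():
            if cname == skip or rng.random() > config.p_context:
                continue
            roll = rng.random()
            if roll < config.p_wildcard:
                state_part = "~?" if states and rng.random() < 0.5 else ""
                out.append(f"{cname}{state_part}!?")
            elif roll < 2 * config.p_wildcard:
                out.append(f"{cname}!+")
            elif states and rng.random() < 0.5:
                out.append(f"{cname}~{rng.choice(states)}")
            else:
                out.append(cname)  # required unbound
        return out

    def fully_specified(tname: str) -> str:
        comps = dict(next(c for n, c in types if n == tname))
        body = ",".join(
            c + (f"~{rng.choice(sts)}" if sts else "") for c, sts in comps.items()
        )
        return f"{tname}({body})"

    stateful = [
        (n, c, sts) for n, comps in types for c, sts in comps if sts
    ]

    lines.append("begin reaction rules")
    for ri in range(1, config.n_rules + 1):
        kinds = ["bind", "unbind", "state", "state", "bind"]
        if rng.random() < 0.15:
            kinds = ["synth", "degrade"]
        kind = rng.choice(kinds)
        if kind == "state" and not stateful:
            kind = "bind"
        reversible = rng.random() < config.p_reversible
        arrow = "<->" if reversible else "->"
        rates = f"k{2 * ri - 1}" + (f", k{2 * ri}" if reversible else "")
        if kind == "synth":
            tname = rng.choice(types)[0]
            lines.append(f"  R{ri}: 0 {arrow} {fully_specified(tname)} {rates}")
            continue
        if kind == "degrade":
            tname = rng.choice(types)[0]
            if reversible:
                lines.append(f"  R{ri}: {fully_specified(tname)} {arrow} 0 {rates}")
            else:
                lines.append(f"  R{ri}: {tname}() {arrow} 0 {rates}")
            continue
        if kind == "state":
            tname, cname, states = rng.choice(stateful)
            before, after = rng.sample(states, 2)
            ctx = context_suffixes(tname, cname)
            lhs = ",".join([f"{cname}~{before}"] + ctx)
            rhs = ",".join([f"{cname}~{after}"] + ctx)
            lines.append(f"  R{ri}: {tname}({lhs}) {arrow} {tname}({rhs}) {rates}")
            continue
        # bind / unbind between two molecules (possibly the same type)
        ta = rng.choice(types)
        tb = rng.choice(types) if config.max_pattern_size >= 2 else ta
        ca = rng.choice(ta[1])[0]
        cb = rng.choice(tb[1])[0]
        ctx_a = context_suffixes(ta[0], ca)
        ctx_b = context_suffixes(tb[0], cb)
        free_a = ",".join([ca] + ctx_a)
        free_b = ",".join([cb] + ctx_b)
        bound_a = ",".join([f"{ca}!1"] + ctx_a)
        bound_b = ",".join([f"{cb}!1"] + ctx_b)
        if ta[0] == tb[0] and ca == cb and config.max_pattern_size < 2:
            kind = "state" if stateful else "bind"
        if kind == "bind" and config.max_pattern_size >= 2:
            lines.append(
                f"  R{ri}: {ta[0]}({free_a}) + {tb[0]}({free_b}) {arrow} "
                f"{ta[0]}({bound_a}).{tb[0]}({bound_b}) {rates}"
            )
        else:
            lines.append(
                f"  R{ri}: {ta[0]}({bound_a}).{tb[0]}({bound_b}) {arrow} "
                f"{ta[0]}({free_a}) + {tb[0]}({free_b}) {rates}"
            )
    lines.append("end reaction rules")

    return parse_model("\n".join(lines) + "\n", name=f"random-{config.seed}")
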