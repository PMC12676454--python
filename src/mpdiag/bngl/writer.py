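"""Serialize models back to BNGL text (round-trip inverse of the parser)."""

from __future__ import annotations

from mpdiag.bngl.model import (
    BondKind,
    ComplexPattern,
    ComponentPattern,
    Model,
    MoleculePattern,
    MoleculeTypeDef,
    Rule,
)

__all__ = ["write_model", "format_complex_pattern", "format_reaction_side"]


def _format_component(comp: ComponentPattern) -> str:
    s = comp.name
    if comp.state is not None:
        s += f"~{comp.state}"
    b = comp.bond
    if b.kind is BondKind.ANY:
        s += "!?"
    elif b.kind is BondKind.BOUND_ANY:
        s += "!+"
    elif b.kind is BondKind.LINK:
        s += f"!{b.index}"
    return s


def _format_molecule(mol: MoleculePattern) -> str:
    prefix = f"@{mol.compartment}:" if mol.compartment else ""
    return f"{prefix}{mol.type_name}({','.join(_format_component(c) for c in mol.components)})"


def format_complex_pattern(cp: ComplexPattern) -> str:
    return ".".join(_format_molecule(m) for m in cp.molecules)


def format_reaction_side(patterns: tuple[ComplexPattern, ...]) -> str:
    if not patterns:
        return "0"
    return " + ".join(format_complex_pattern(p) for p in patterns)


def _format_molecule_type(t: MoleculeTypeDef) -> str:
    comps = ",".join(c.name + "".join(f"~{s}" for s in c.states) for c in t.components)
    return f"{t.name}({comps})"


def _format_rule(rule: Rule) -> str:
    arrow = "<->" if rule.reversible else "->"
    rates = rule.rate_forward + (f", {rule.rate_reverse}" if rule.reversible else "")
    label = f"{rule.name}: " if rule.name else ""
    return (
        f"{label}{format_reaction_side(rule.reactants)} {arrow} "
        f"{format_reaction_side(rule.products)} {rates}"
    )


def write_model(model: Model) -> str:
    """Render a model as BNGL; ``parse_model(write_model(m))`` equals ``m``.

    Equality is structural: rule ids survive because named rules keep their
    names and unnamed rules are re-assigned the same positional ids.
    """
    lines: list[str] = []
    if model.parameters:
        lines.append("begin parameters")
        lines.extend(f"  {name} {expr}" for name, expr in model.parameters)
        lines.append("end parameters")
    if model.compartments:
        lines.append("begin compartments")
        for name, dim, extra in model.compartments:
            lines.append(f"  {name} {dim} {extra}".rstrip())
        lines.append("end compartments")
    lines.append("begin molecule types")
    lines.extend(f"  {_format_molecule_type(t)}" for t in model.molecule_types)
    lines.append("end molecule types")
    if model.seed_species:
        lines.append("begin seed species")
        lines.extend(f"  {format_complex_pattern(cp)} {amount}" for cp, amount in model.seed_species)
        lines.append("end seed species")
    if model.observables_raw:
        lines.append("begin observables")
        lines.extend(f"  {line}" for line in model.observables_raw)
        lines.append("end observables")
    if model.functions_raw:
        lines.append("begin functions")
        lines.extend(f"  {line}" for line in model.functions_raw)
        lines.append("end functions")
    lines.append("begin reaction rules")
    lines.extend(f"  {_format_rule(r)}" for r in model.rules)
    lines.append("end reaction rules")
    return "\n".join(lines) + "\n"
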