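"""Construct molecular process diagrams: bipartite graphs of molecular-complex
nodes and process nodes, at three resolution levels.

Level 1 shows only complexes, processes and stoichiometric arcs; level 2 adds
modified-site labels to arcs; level 3 adds required-context labels to
consumption arcs.  Nodes and arcs are identical across levels — only the
annotations grow — so the levels are views of one underlying graph.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from mpdiag.bngl.model import ComplexPattern, Model, Rule
from mpdiag.semantics import (
    MODIFIED_LABELS,
    REACTANT,
    BondEvent,
    SiteClassification,
    SiteLabel,
    classify_rule,
)

__all__ = [
    "CONSUMPTION",
    "PRODUCTION",
    "ComplexNode",
    "ProcessNode",
    "MPDArc",
    "MPDGraph",
    "composition_key",
    "display_label",
    "build_mpd",
    "mpd_stats",
]

CONSUMPTION = "consumption"
PRODUCTION = "production"


def composition_key(pattern: ComplexPattern) -> str:
    """The sorted multiset of (type name, compartment) as a string.

    States and bond topology are deliberately ignored: all patterns with the
    same molecular composition collapse onto one complex node.
    """
    items = sorted(
        m.type_name + (f"@{m.compartment}" if m.compartment else "")
        for m in pattern.molecules
    )
    return "|".join(items)


def display_label(key: str) -> str:
    return "·".join(key.split("|"))


@dataclass(frozen=True)
class ComplexNode:
    composition_key: str
    display_label: str
    member_patterns: tuple[tuple[str, str, int], ...]  # (rule_id, side, pattern index)


@dataclass(frozen=True)
class ProcessNode:
    rule_id: str
    reversible: bool
    ordinal: int  # 1-based file order


@dataclass(frozen=True)
class MPDArc:
    kind: str  # consumption: complex -> process; production: process -> complex
    complex_key: str
    rule_id: str
    stoichiometry: int
    site_labels: tuple[str, ...] = ()
    context_labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class MPDGraph:
    complex_nodes: tuple[ComplexNode, ...]
    process_nodes: tuple[ProcessNode, ...]
    arcs: tuple[MPDArc, ...]
    level: int
    provenance: tuple[tuple[str, str], ...] = ()
    molecule_types: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def complex_id(self, key: str) -> str:
        for i, node in enumerate(self.complex_nodes):
            if node.composition_key == key:
                return f"c{i}"
        raise KeyError(key)

    def process_id(self, rule_id: str) -> str:
        for node in self.process_nodes:
            if node.rule_id == rule_id:
                return f"p{node.ordinal}"
        raise KeyError(rule_id)


def _fmt_state(s: str | None) -> str:
    return s if s is not None else "?"


def _label_maps(cls: SiteClassification) -> dict[tuple[str, str], str]:
    """Display name per (type, comp): bare unless the comp name is shared by
    several molecule types within this rule."""
    by_comp: dict[str, set[str]] = {}
    for entry in cls.entries.values():
        by_comp.setdefault(entry.comp_name, set()).add(entry.type_name)
    names: dict[tuple[str, str], str] = {}
    for entry in cls.entries.values():
        key = (entry.type_name, entry.comp_name)
        if len(by_comp[entry.comp_name]) > 1:
            names[key] = f"{entry.type_name}.{entry.comp_name}"
        else:
            names[key] = entry.comp_name
    return names


def _bond_event_label(verb: str, ev: BondEvent, names: dict[tuple[str, str], str]) -> str:
    a = names[(ev.a.type_name, ev.a.comp_name)]
    b = names[(ev.b.type_name, ev.b.comp_name)]
    return f"{verb}@{a}–{b}"


def _dedup(labels: Iterable[str]) -> tuple[str, ...]:
    seen: set[str] = set()
    out: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen.add(lab)
            out.append(lab)
    return tuple(out)


def build_mpd(model: Model, level: int = 1) -> MPDGraph:
    """Build the diagram at the requested level.

    One process node per rule (reversible rules still map to a single node);
    one complex node per distinct composition key across all reactant and
    product patterns; consumption/production arcs merged by composition key
    with the merged multiplicity as stoichiometry.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"level must be 1, 2 or 3, got {level!r}")
    model.validate()
    types = model.types_by_name()

    members: dict[str, list[tuple[str, str, int]]] = {}
    arcs: list[MPDArc] = []
    processes: list[ProcessNode] = []

    for ordinal, rule in enumerate(model.rules, start=1):
        processes.append(ProcessNode(rule_id=rule.id, reversible=rule.reversible, ordinal=ordinal))
        r_keys = [composition_key(p) for p in rule.reactants]
        p_keys = [composition_key(p) for p in rule.products]
        for side, keys in ((REACTANT, r_keys), ("product", p_keys)):
            for pi, key in enumerate(keys):
                members.setdefault(key, []).append((rule.id, side, pi))

        cons_site: dict[str, list[str]] = {}
        prod_site: dict[str, list[str]] = {}
        cons_ctx: dict[str, list[str]] = {}
        if level >= 2:
            corr, cls = classify_rule(rule, types)
            r2p = dict(corr.pairs)
            names = _label_maps(cls)
            for ref, entry in sorted(cls.entries.items()):
                disp = names[(entry.type_name, entry.comp_name)]
                if ref.side == REACTANT and entry.label in MODIFIED_LABELS and entry.state_changed:
                    lab = f"{_fmt_state(entry.before_state)}→{_fmt_state(entry.after_state)}@{disp}"
                    if ref.pattern < len(r_keys):
                        cons_site.setdefault(r_keys[ref.pattern], []).append(lab)
                    partner = r2p.get(ref.occurrence)
                    if partner is not None:
                        prod_site.setdefault(p_keys[partner.pattern], []).append(lab)
                if level >= 3 and ref.side == REACTANT and entry.label is SiteLabel.CONTEXT:
                    ctx = cons_ctx.setdefault(r_keys[ref.pattern], [])
                    if entry.before_state is not None:
                        ctx.append(f"{entry.before_state}@{disp}")
                    if entry.before_bond == "unbound":
                        ctx.append(f"unbound@{disp}")
                    elif entry.before_bond == "bound":
                        ctx.append(f"bound@{disp}")
            # binding changes go on consumption arcs only
            for verb, events in (("bond", cls.formed_bonds), ("unbind", cls.broken_bonds)):
                for ev in events:
                    lab = _bond_event_label(verb, ev, names)
                    for end in (ev.a, ev.b):
                        if end.ref.side == REACTANT and end.ref.pattern < len(r_keys):
                            cons_site.setdefault(r_keys[end.ref.pattern], []).append(lab)
            # bond-class changes without an explicit partner pair (e.g. '!+' released)
            event_refs = {
                end.ref
                for evs in (cls.formed_bonds, cls.broken_bonds)
                for ev in evs
                for end in (ev.a, ev.b)
            }
            for ref, entry in sorted(cls.entries.items()):
                if (
                    ref.side == REACTANT
                    and entry.bond_changed
                    and ref not in event_refs
                    and entry.before_bond != entry.after_bond
                    and entry.after_bond is not None
                ):
                    disp = names[(entry.type_name, entry.comp_name)]
                    cons_site.setdefault(r_keys[ref.pattern], []).append(
                        f"{entry.before_bond}→{entry.after_bond}@{disp}"
                    )

        for kind, keys, site_map, ctx_map in (
            (CONSUMPTION, r_keys, cons_site, cons_ctx),
            (PRODUCTION, p_keys, prod_site, {}),
        ):
            counts = Counter(keys)
            order: list[str] = []
            for key in keys:
                if key not in order:
                    order.append(key)
            for key in order:
                arcs.append(
                    MPDArc(
                        kind=kind,
                        complex_key=key,
                        rule_id=rule.id,
                        stoichiometry=counts[key],
                        site_labels=_dedup(site_map.get(key, ())),
                        context_labels=_dedup(ctx_map.get(key, ())),
                    )
                )

    complex_nodes = tuple(
        ComplexNode(
            composition_key=key,
            display_label=display_label(key),
            member_patterns=tuple(members[key]),
        )
        for key in sorted(members)
    )
    mol_types = tuple((t.name, t.component_names()) for t in model.molecule_types)
    return MPDGraph(
        complex_nodes=complex_nodes,
        process_nodes=tuple(processes),
        arcs=tuple(arcs),
        level=level,
        provenance=tuple(
            sorted(
                {
                    "model": model.name,
                    "builder": "mpdiag.build_mpd",
                    "reversible_rules_merged": "true",
                }.items()
            )
        ),
        molecule_types=mol_types,
    )


def mpd_stats(graph: MPDGraph) -> dict[str, int]:
    """Summary counts for a diagram."""
    return {
        "level": graph.level,
        "process_count": len(graph.process_nodes),
        "complex_count": len(graph.complex_nodes),
        "arc_count": len(graph.arcs),
        "consumption_count": sum(1 for a in graph.arcs if a.kind == CONSUMPTION),
        "production_count": sum(1 for a in graph.arcs if a.kind == PRODUCTION),
        "site_label_count": sum(len(a.site_labels) for a in graph.arcs),
        "context_label_count": sum(len(a.context_labels) for a in graph.arcs),
    }
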