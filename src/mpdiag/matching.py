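"""Brute-force pattern matching, single-rule expansion and state enumeration.

This module is the concrete-semantics oracle for the rest of the package: a
pattern either embeds into a fully specified species or it does not, and a
rule applied under an embedding yields fully specified product species.  All
searches are exhaustive and deterministic; patterns and species in rules are
small, so no indexing or hashing shortcuts are taken.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from mpdiag.errors import ExpansionOverflowError, ModelValidationError, UnsupportedRuleError
from mpdiag.bngl.canonical import canonical_form
from mpdiag.bngl.model import (
    BondKind,
    ComplexPattern,
    ComponentPattern,
    Model,
    MoleculePattern,
    MoleculeTypeDef,
    Rule,
    link,
    resolve_components,
    validate_pattern,
)
from mpdiag.semantics import PRODUCT, REACTANT, SiteRef, classify_rule

__all__ = [
    "ConcreteSpecies",
    "ConcreteReaction",
    "ExpansionResult",
    "ApplyResult",
    "match",
    "apply_rule",
    "expand_rule",
    "enumerate_states",
    "iter_state_combinations",
]


@dataclass(frozen=True)
class ConcreteSpecies:
    """A fully specified species: every component listed, no wildcards."""

    pattern: ComplexPattern
    canonical: str

    @classmethod
    def from_pattern(
        cls, pattern: ComplexPattern, types: Mapping[str, MoleculeTypeDef]
    ) -> "ConcreteSpecies":
        validate_pattern(pattern, types, where="concrete species")
        for mol in pattern.molecules:
            tdef = types[mol.type_name]
            if len(mol.components) != len(tdef.components):
                raise ModelValidationError(
                    f"species molecule {mol.type_name} must list all "
                    f"{len(tdef.components)} components"
                )
            slots = resolve_components(mol, tdef)
            for comp, slot in zip(mol.components, slots):
                cdef = tdef.components[slot]
                if cdef.states and comp.state_value is None:
                    raise ModelValidationError(
                        f"species site {mol.type_name}.{comp.name} needs a concrete state"
                    )
                if comp.bond.kind in (BondKind.ANY, BondKind.BOUND_ANY):
                    raise ModelValidationError(
                        f"species site {mol.type_name}.{comp.name} carries a bond wildcard"
                    )
        return cls(pattern=pattern, canonical=canonical_form(pattern))

    def __hash__(self) -> int:
        return hash(self.canonical)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ConcreteSpecies) and self.canonical == other.canonical


# ---------------------------------------------------------------------------
# internal mutable species graph


@dataclass
class _Mol:
    type_name: str
    compartment: str | None
    states: list[str | None]
    bonds: list[tuple[int, int] | None]  # per slot: (partner mol id, partner slot)


def _species_to_graph(
    species: ConcreteSpecies, types: Mapping[str, MoleculeTypeDef], id_offset: int = 0
) -> dict[int, _Mol]:
    graph: dict[int, _Mol] = {}
    link_ends: dict[int, list[tuple[int, int]]] = {}
    for mi, mol in enumerate(species.pattern.molecules):
        tdef = types[mol.type_name]
        slots = resolve_components(mol, tdef)
        states: list[str | None] = [None] * len(tdef.components)
        bonds: list[tuple[int, int] | None] = [None] * len(tdef.components)
        for comp, slot in zip(mol.components, slots):
            states[slot] = comp.state_value
            if comp.bond.kind is BondKind.LINK:
                link_ends.setdefault(comp.bond.index, []).append((id_offset + mi, slot))
        graph[id_offset + mi] = _Mol(mol.type_name, mol.compartment, states, bonds)
    for eps in link_ends.values():
        (a, sa), (b, sb) = eps
        graph[a].bonds[sa] = (b, sb)
        graph[b].bonds[sb] = (a, sa)
    return graph


def _graph_to_species(
    graph: dict[int, _Mol], mol_ids: Sequence[int], types: Mapping[str, MoleculeTypeDef]
) -> ConcreteSpecies:
    index = {mid: i for i, mid in enumerate(mol_ids)}
    bond_labels: dict[frozenset[tuple[int, int]], int] = {}
    molecules: list[MoleculePattern] = []
    for mid in mol_ids:
        mol = graph[mid]
        tdef = types[mol.type_name]
        comps: list[ComponentPattern] = []
        for slot, cdef in enumerate(tdef.components):
            bond = mol.bonds[slot]
            if bond is None:
                from mpdiag.bngl.model import UNBOUND

                bspec = UNBOUND
            else:
                key = frozenset({(mid, slot), bond})
                label = bond_labels.setdefault(key, len(bond_labels) + 1)
                bspec = link(label)
            comps.append(ComponentPattern(name=cdef.name, state=mol.states[slot], bond=bspec))
        molecules.append(
            MoleculePattern(
                type_name=mol.type_name, components=tuple(comps), compartment=mol.compartment
            )
        )
    pattern = ComplexPattern(molecules=tuple(molecules))
    return ConcreteSpecies.from_pattern(pattern, types)


def _connected_components(graph: dict[int, _Mol]) -> list[list[int]]:
    seen: set[int] = set()
    comps: list[list[int]] = []
    for start in sorted(graph):
        if start in seen:
            continue
        stack = [start]
        comp: list[int] = []
        seen.add(start)
        while stack:
            mid = stack.pop()
            comp.append(mid)
            for bond in graph[mid].bonds:
                if bond is not None and bond[0] not in seen:
                    seen.add(bond[0])
                    stack.append(bond[0])
        comps.append(sorted(comp))
    return comps


# ---------------------------------------------------------------------------
# matching


def match(
    pattern: ComplexPattern,
    species: ConcreteSpecies,
    types: Mapping[str, MoleculeTypeDef],
) -> list[tuple[int, ...]]:
    """All injective embeddings of ``pattern`` into ``species``.

    An embedding is a tuple mapping each pattern molecule index to a species
    molecule index.  Components map positionally (duplicate names
    left-to-right).  Results are in deterministic depth-first order.
    """
    graph = _species_to_graph(species, types)
    n = len(pattern.molecules)
    slots_per_mol = [
        resolve_components(mol, types[mol.type_name]) for mol in pattern.molecules
    ]

    def component_ok(comp: ComponentPattern, target: _Mol, slot: int) -> bool:
        if comp.state_value is not None and target.states[slot] != comp.state_value:
            return False
        k = comp.bond.kind
        bonded = target.bonds[slot] is not None
        if k is BondKind.UNBOUND:
            return not bonded
        if k is BondKind.BOUND_ANY or k is BondKind.LINK:
            return bonded
        return True  # ANY

    def molecule_ok(pi: int, target_id: int) -> bool:
        mol = pattern.molecules[pi]
        target = graph[target_id]
        if mol.type_name != target.type_name:
            return False
        if mol.compartment is not None and mol.compartment != target.compartment:
            return False
        return all(
            component_ok(comp, target, slot)
            for comp, slot in zip(mol.components, slots_per_mol[pi])
        )

    embeddings: list[tuple[int, ...]] = []
    assignment: list[int] = []
    used: set[int] = set()

    def bonds_ok(assign: Sequence[int]) -> bool:
        for eps in pattern.bond_endpoints().values():
            (ma, ca), (mb, cb) = eps
            sa = slots_per_mol[ma][ca]
            sb = slots_per_mol[mb][cb]
            if graph[assign[ma]].bonds[sa] != (assign[mb], sb):
                return False
        return True

    def extend(pi: int) -> None:
        if pi == n:
            if bonds_ok(assignment):
                embeddings.append(tuple(assignment))
            return
        for target_id in sorted(graph):
            if target_id in used or not molecule_ok(pi, target_id):
                continue
            used.add(target_id)
            assignment.append(target_id)
            extend(pi + 1)
            assignment.pop()
            used.remove(target_id)

    extend(0)
    return embeddings


# ---------------------------------------------------------------------------
# rule application and expansion


@dataclass(frozen=True)
class ConcreteReaction:
    """One concrete instantiation of a rule (identity by species multisets)."""

    rule_id: str
    reactants: tuple[str, ...]  # sorted canonical strings
    products: tuple[str, ...]
    embedding: tuple[tuple[int, ...], ...]  # one molecule map per reactant pattern


@dataclass
class ApplyResult:
    products: list[ConcreteSpecies]
    before: dict[int, _Mol]
    after: dict[int, _Mol]


@dataclass
class ExpansionResult:
    reactions: tuple[ConcreteReaction, ...]
    species: tuple[ConcreteSpecies, ...]
    fixed_point: bool
    iterations: int


def _copy_graph(graph: dict[int, _Mol]) -> dict[int, _Mol]:
    return {
        mid: _Mol(m.type_name, m.compartment, list(m.states), list(m.bonds))
        for mid, m in graph.items()
    }


def _break_bond(graph: dict[int, _Mol], mid: int, slot: int) -> None:
    bond = graph[mid].bonds[slot]
    if bond is not None:
        pm, ps = bond
        graph[pm].bonds[ps] = None
        graph[mid].bonds[slot] = None


def apply_rule(
    model: Model,
    rule: Rule,
    species_list: Sequence[ConcreteSpecies],
    embeddings: Sequence[tuple[int, ...]],
) -> ApplyResult:
    """Apply ``rule`` to one species instance per reactant pattern.

    ``species_list[i]`` is matched by reactant pattern ``i`` under
    ``embeddings[i]``.  Returns the product species together with the
    before/after concrete graphs (stable molecule instance ids) so callers can
    verify the induced site-level changes independently.
    """
    types = model.types_by_name()
    corr, cls = classify_rule(rule, types)

    # disjoint union of the reactant species instances
    graph: dict[int, _Mol] = {}
    offsets: list[int] = []
    next_id = 0
    for sp in species_list:
        offsets.append(next_id)
        graph.update(_species_to_graph(sp, types, id_offset=next_id))
        next_id += len(sp.pattern.molecules)
    before = _copy_graph(graph)

    def glob(ref_side: str, pattern: int, mol: int) -> int:
        if ref_side != REACTANT:
            raise AssertionError("only reactant occurrences have pre-existing images")
        return offsets[pattern] + embeddings[pattern][mol]

    # 1. state changes on paired molecules
    for ref, entry in cls.entries.items():
        if ref.side != REACTANT or not entry.state_changed:
            continue
        if ref.occurrence in set(corr.destroyed):
            continue
        if entry.after_state is None:
            raise UnsupportedRuleError(
                f"rule {rule.id}: product leaves state of "
                f"{entry.type_name}.{entry.comp_name} unspecified"
            )
        graph[glob(REACTANT, ref.pattern, ref.mol)].states[ref.comp] = entry.after_state

    # 2. break bonds: explicit broken events, then class changes to unbound
    for ev in cls.broken_bonds:
        for end in (ev.a, ev.b):
            if end.ref.side == REACTANT:
                _break_bond(graph, glob(REACTANT, end.ref.pattern, end.ref.mol), end.ref.comp)
    event_refs = {
        end.ref
        for evs in (cls.formed_bonds, cls.broken_bonds)
        for ev in evs
        for end in (ev.a, ev.b)
    }
    destroyed_occs = set(corr.destroyed)
    for ref, entry in cls.entries.items():
        if (
            ref.side == REACTANT
            and entry.bond_changed
            and entry.after_bond == "unbound"
            and ref not in event_refs
            and ref.occurrence not in destroyed_occs
        ):
            _break_bond(graph, glob(REACTANT, ref.pattern, ref.mol), ref.comp)

    # 3. destroy surplus reactant molecules
    for occ in corr.destroyed:
        mid = glob(REACTANT, occ.pattern, occ.mol)
        for slot in range(len(graph[mid].bonds)):
            _break_bond(graph, mid, slot)
        del graph[mid]

    # 4. instantiate created molecules (must be fully specified)
    created_ids: dict[tuple[int, int], int] = {}
    nonlocal_next = next_id
    for occ in corr.created:
        mol = rule.products[occ.pattern].molecules[occ.mol]
        tdef = types[mol.type_name]
        states: list[str | None] = [None] * len(tdef.components)
        slots = resolve_components(mol, tdef)
        listed = dict(zip(slots, mol.components))
        for slot, cdef in enumerate(tdef.components):
            comp = listed.get(slot)
            if comp is None:
                if cdef.states:
                    raise UnsupportedRuleError(
                        f"rule {rule.id}: created molecule {mol.type_name} leaves "
                        f"component {cdef.name} unspecified"
                    )
                continue
            if comp.bond.kind in (BondKind.ANY, BondKind.BOUND_ANY):
                raise UnsupportedRuleError(
                    f"rule {rule.id}: created molecule {mol.type_name}.{comp.name} "
                    "carries a bond wildcard"
                )
            if cdef.states:
                if comp.state_value is None:
                    raise UnsupportedRuleError(
                        f"rule {rule.id}: created molecule {mol.type_name}.{cdef.name} "
                        "has no concrete state"
                    )
                states[slot] = comp.state_value
        created_ids[(occ.pattern, occ.mol)] = nonlocal_next
        graph[nonlocal_next] = _Mol(
            mol.type_name, mol.compartment, states, [None] * len(tdef.components)
        )
        nonlocal_next += 1

    # 5. form bonds required by the product side
    p2r = {p: r for r, p in corr.pairs}

    def image_of(ref: SiteRef) -> int:
        if ref.side == REACTANT:
            return glob(REACTANT, ref.pattern, ref.mol)
        if (ref.pattern, ref.mol) in created_ids:
            return created_ids[(ref.pattern, ref.mol)]
        mapped = p2r[ref.occurrence]
        return glob(REACTANT, mapped.pattern, mapped.mol)

    for ev in cls.formed_bonds:
        (ia, sa), (ib, sb) = (
            (image_of(ev.a.ref), ev.a.ref.comp),
            (image_of(ev.b.ref), ev.b.ref.comp),
        )
        _break_bond(graph, ia, sa)
        _break_bond(graph, ib, sb)
        graph[ia].bonds[sa] = (ib, sb)
        graph[ib].bonds[sb] = (ia, sa)

    products = [
        _graph_to_species(graph, comp, types) for comp in _connected_components(graph)
    ]
    return ApplyResult(products=products, before=before, after=graph)


def expand_rule(
    model: Model,
    rule: Rule,
    seeds: Sequence[ConcreteSpecies],
    max_iterations: int = 1,
    species_cap: int = 10_000,
) -> ExpansionResult:
    """Exhaustively instantiate ``rule`` over a growing species pool.

    Reactions are deduplicated by canonical reactant/product multisets, which
    also collapses embeddings differing only by pattern automorphisms.  With
    ``max_iterations > 1`` newly produced species re-enter the pool until a
    fixed point or the iteration cap; exceeding ``species_cap`` raises
    :class:`ExpansionOverflowError` rather than truncating silently.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    types = model.types_by_name()
    pool: dict[str, ConcreteSpecies] = {}
    for sp in seeds:
        pool.setdefault(sp.canonical, sp)
    reactions: dict[tuple, ConcreteReaction] = {}
    fixed_point = False
    iterations = 0
    for _ in range(max_iterations):
        iterations += 1
        grew = False
        pool_list = list(pool.values())
        for combo in itertools.product(pool_list, repeat=len(rule.reactants)):
            per_pattern = [match(p, s, types) for p, s in zip(rule.reactants, combo)]
            if any(not e for e in per_pattern):
                continue
            for embset in itertools.product(*per_pattern):
                result = apply_rule(model, rule, combo, embset)
                key = (
                    tuple(sorted(s.canonical for s in combo)),
                    tuple(sorted(s.canonical for s in result.products)),
                )
                if key not in reactions:
                    reactions[key] = ConcreteReaction(
                        rule_id=rule.id,
                        reactants=key[0],
                        products=key[1],
                        embedding=tuple(embset),
                    )
                    grew = True
                for sp in result.products:
                    if sp.canonical not in pool:
                        pool[sp.canonical] = sp
                        grew = True
                        if len(pool) > species_cap:
                            raise ExpansionOverflowError(species_cap)
        if not grew:
            fixed_point = True
            break
    return ExpansionResult(
        reactions=tuple(reactions.values()),
        species=tuple(pool.values()),
        fixed_point=fixed_point,
        iterations=iterations,
    )


# ---------------------------------------------------------------------------
# state enumeration


def enumerate_states(mt: MoleculeTypeDef) -> int:
    """Number of internal-state combinations of one molecule (bonds ignored)."""
    count = 1
    for comp in mt.components:
        count *= max(1, len(comp.states))
    return count


def iter_state_combinations(mt: MoleculeTypeDef) -> Iterator[tuple[str | None, ...]]:
    """Lazily yield every internal-state assignment, one entry per component."""
    choices = [comp.states if comp.states else (None,) for comp in mt.components]
    yield from itertools.product(*choices)
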