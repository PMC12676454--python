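"""Core domain types for rule-based models in the supported BNGL dialect.

A model is a set of molecule type declarations plus an ordered list of
reaction rules written over *patterns*: partially specified molecules whose
components carry state and bond constraints.  Pattern semantics follow BNGL
conventions:

* a component omitted from a pattern is unconstrained (any state, any bond);
* a component listed without a ``~state`` has no state constraint;
* a component listed without a ``!`` bond suffix must be **unbound**;
* ``!?`` leaves bonding unconstrained, ``!+`` requires a bond to an
  unspecified partner, ``!n`` names an explicit bond endpoint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Mapping

from mpdiag.errors import ModelValidationError

__all__ = [
    "BondKind",
    "BondSpec",
    "ANY_BOND",
    "UNBOUND",
    "BOUND_ANY",
    "link",
    "bond_class",
    "ComponentDef",
    "MoleculeTypeDef",
    "ComponentPattern",
    "MoleculePattern",
    "ComplexPattern",
    "Rule",
    "Model",
    "resolve_components",
    "validate_pattern",
]


class BondKind(Enum):
    ANY = "?"
    UNBOUND = "."
    BOUND_ANY = "+"
    LINK = "!"


@dataclass(frozen=True)
class BondSpec:
    """A bond constraint on a single component."""

    kind: BondKind
    index: int | None = None

    def __post_init__(self) -> None:
        if self.kind is BondKind.LINK:
            if self.index is None or self.index < 1:
                raise ModelValidationError("explicit bond requires a positive index")
        elif self.index is not None:
            raise ModelValidationError(f"bond kind {self.kind.name} takes no index")


ANY_BOND = BondSpec(BondKind.ANY)
UNBOUND = BondSpec(BondKind.UNBOUND)
BOUND_ANY = BondSpec(BondKind.BOUND_ANY)


def link(index: int) -> BondSpec:
    return BondSpec(BondKind.LINK, index)


def bond_class(bond: BondSpec) -> str:
    """Collapse a bond constraint to its class: ``any``, ``unbound`` or ``bound``.

    Both ``!n`` and ``!+`` count as ``bound``; the class is the granularity at
    which bond *changes* are detected.
    """
    if bond.kind is BondKind.ANY:
        return "any"
    if bond.kind is BondKind.UNBOUND:
        return "unbound"
    return "bound"


@dataclass(frozen=True)
class ComponentDef:
    """A component (site) declaration within a molecule type."""

    name: str
    states: tuple[str, ...] = ()


@dataclass(frozen=True)
class MoleculeTypeDef:
    name: str
    components: tuple[ComponentDef, ...] = ()

    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)


@dataclass(frozen=True)
class ComponentPattern:
    """A component occurrence inside a molecule pattern.

    ``state`` is ``None`` when no ``~`` was written and ``"?"`` for an explicit
    ``~?`` wildcard; both mean "any state".  The distinction is kept only so a
    parsed model writes back exactly as it was read.
    """

    name: str
    state: str | None = None
    bond: BondSpec = UNBOUND

    @property
    def state_is_any(self) -> bool:
        return self.state is None or self.state == "?"

    @property
    def state_value(self) -> str | None:
        """The concrete state constraint, or None when unconstrained."""
        return None if self.state_is_any else self.state


@dataclass(frozen=True)
class MoleculePattern:
    type_name: str
    components: tuple[ComponentPattern, ...] = ()
    compartment: str | None = None


@dataclass(frozen=True)
class ComplexPattern:
    """A connected multiset of molecule patterns joined by explicit bonds."""

    molecules: tuple[MoleculePattern, ...]

    def bond_endpoints(self) -> dict[int, list[tuple[int, int]]]:
        """Map each bond index to its [(molecule index, component index), ...]."""
        out: dict[int, list[tuple[int, int]]] = {}
        for mi, mol in enumerate(self.molecules):
            for ci, comp in enumerate(mol.components):
                if comp.bond.kind is BondKind.LINK:
                    out.setdefault(comp.bond.index, []).append((mi, ci))
        return out


@dataclass(frozen=True)
class Rule:
    """A reaction rule: reactant patterns, product patterns, rates."""

    id: str
    reactants: tuple[ComplexPattern, ...]
    products: tuple[ComplexPattern, ...]
    rate_forward: str
    reversible: bool = False
    rate_reverse: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.reversible != (self.rate_reverse is not None):
            raise ModelValidationError(
                f"rule {self.id}: rate_reverse must be present iff the rule is reversible"
            )

    def reversed(self) -> "Rule":
        """The same transformation read right-to-left (products become reactants)."""
        return replace(
            self,
            reactants=self.products,
            products=self.reactants,
            rate_forward=self.rate_reverse if self.reversible else self.rate_forward,
            rate_reverse=self.rate_forward if self.reversible else None,
        )


@dataclass
class Model:
    """A parsed (or programmatically built) rule-based model."""

    molecule_types: tuple[MoleculeTypeDef, ...]
    rules: tuple[Rule, ...] = ()
    parameters: tuple[tuple[str, str], ...] = ()
    seed_species: tuple[tuple[ComplexPattern, str], ...] = ()
    compartments: tuple[tuple[str, int, str], ...] = ()
    observables_raw: tuple[str, ...] = ()
    functions_raw: tuple[str, ...] = ()
    name: str = field(default="model", compare=False)  # metadata, not structure

    def types_by_name(self) -> dict[str, MoleculeTypeDef]:
        return {t.name: t for t in self.molecule_types}

    def rule_by_id(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    def validate(self) -> None:
        types = self.types_by_name()
        if len(types) != len(self.molecule_types):
            seen: set[str] = set()
            for t in self.molecule_types:
                if t.name in seen:
                    raise ModelValidationError(f"duplicate molecule type {t.name!r}")
                seen.add(t.name)
        for t in self.molecule_types:
            if not t.name:
                raise ModelValidationError("molecule type with empty name")
        for rule in self.rules:
            for side, patterns in (("reactant", rule.reactants), ("product", rule.products)):
                for pi, cp in enumerate(patterns):
                    validate_pattern(cp, types, where=f"rule {rule.id} {side} {pi}")
        for si, (cp, _amount) in enumerate(self.seed_species):
            validate_pattern(cp, types, where=f"seed species {si}")


def resolve_components(mol: MoleculePattern, tdef: MoleculeTypeDef) -> tuple[int, ...]:
    """Resolve each pattern component to a component slot of the type.

    Duplicate component names bind left-to-right: each pattern occurrence takes
    the leftmost unused type occurrence of that name.
    """
    used: set[int] = set()
    out: list[int] = []
    names = tdef.component_names()
    for comp in mol.components:
        for ti, tname in enumerate(names):
            if tname == comp.name and ti not in used:
                used.add(ti)
                out.append(ti)
                break
        else:
            raise ModelValidationError(
                f"component {comp.name!r} not available on molecule type {tdef.name!r}"
            )
    return tuple(out)


def validate_pattern(
    cp: ComplexPattern, types: Mapping[str, MoleculeTypeDef], where: str = "pattern"
) -> None:
    """Check type references, state legality, bond pairing and connectivity."""
    if not cp.molecules:
        raise ModelValidationError(f"{where}: empty complex pattern")
    for mi, mol in enumerate(cp.molecules):
        tdef = types.get(mol.type_name)
        if tdef is None:
            raise ModelValidationError(f"{where}: undeclared molecule type {mol.type_name!r}")
        slots = resolve_components(mol, tdef)
        for comp, slot in zip(mol.components, slots):
            allowed = tdef.components[slot].states
            if comp.state_value is not None and comp.state_value not in allowed:
                raise ModelValidationError(
                    f"{where}: state {comp.state_value!r} not allowed for "
                    f"{mol.type_name}.{comp.name} (allowed: {allowed})"
                )
    endpoints = cp.bond_endpoints()
    for idx, eps in endpoints.items():
        if len(eps) != 2:
            raise ModelValidationError(
                f"{where}: bond index {idx} has {len(eps)} endpoint(s); exactly 2 required"
            )
    # connectivity over the bond graph
    n = len(cp.molecules)
    if n > 1:
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for eps in endpoints.values():
            (a, _), (b, _) = eps
            parent[find(a)] = find(b)
        roots = {find(i) for i in range(n)}
        if len(roots) > 1:
            raise ModelValidationError(
                f"{where}: complex pattern is not connected ({len(roots)} components)"
            )


def iter_all_sites(cp: ComplexPattern) -> Iterator[tuple[int, int, ComponentPattern]]:
    """Yield (molecule index, component index, component) over a complex pattern."""
    for mi, mol in enumerate(cp.molecules):
        for ci, comp in enumerate(mol.components):
            yield mi, ci, comp
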