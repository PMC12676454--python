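"""Canonical string labels for complex patterns.

Two patterns receive the same canonical string iff they are isomorphic: there
is a bijection of molecules (and positional component slots) preserving type
names, compartments, component names, state constraints, bond constraints and
bond topology.  The algorithm is exhaustive permutation canonicalization with
a pre-sort on an index-free molecule signature; patterns occurring in rules
are small (≲10 molecules), so correctness is preferred over speed.
"""

from __future__ import annotations

import itertools

from mpdiag.bngl.model import BondKind, ComplexPattern, ComponentPattern, MoleculePattern

__all__ = ["canonical_form"]


def _component_semantic(comp: ComponentPattern, bond_token: str) -> str:
    s = comp.name
    if comp.state_value is not None:
        s += f"~{comp.state_value}"
    s += bond_token
    return s


def _bond_token(comp: ComponentPattern, label: str) -> str:
    k = comp.bond.kind
    if k is BondKind.UNBOUND:
        return ""
    if k is BondKind.ANY:
        return "!?"
    if k is BondKind.BOUND_ANY:
        return "!+"
    return f"!{label}"


def _droppable(mol: MoleculePattern, comp: ComponentPattern) -> bool:
    # a fully unconstrained listed component equals an omitted one, but only
    # drop it when the name is unique in the pattern (positional binding of
    # duplicate names would otherwise shift)
    if comp.state_value is not None or comp.bond.kind is not BondKind.ANY:
        return False
    return sum(1 for c in mol.components if c.name == comp.name) == 1


def _molecule_signature(mol: MoleculePattern) -> str:
    """Index-free rendering used to pre-sort and group molecules."""
    parts = []
    for comp in mol.components:
        if _droppable(mol, comp):
            continue
        parts.append(_component_semantic(comp, _bond_token(comp, "#")))
    prefix = f"@{mol.compartment}:" if mol.compartment else ""
    return f"{prefix}{mol.type_name}({','.join(parts)})"


def _render(cp: ComplexPattern, order: tuple[int, ...]) -> str:
    labels: dict[int, int] = {}
    rendered = []
    for mi in order:
        mol = cp.molecules[mi]
        parts = []
        for comp in mol.components:
            if _droppable(mol, comp):
                continue
            if comp.bond.kind is BondKind.LINK:
                lab = labels.setdefault(comp.bond.index, len(labels) + 1)
                token = f"!{lab}"
            else:
                token = _bond_token(comp, "")
            parts.append(_component_semantic(comp, token))
        prefix = f"@{mol.compartment}:" if mol.compartment else ""
        rendered.append(f"{prefix}{mol.type_name}({','.join(parts)})")
    return ".".join(rendered)


def canonical_form(cp: ComplexPattern) -> str:
    """Return the lexicographically minimal rendering over admissible orders."""
    n = len(cp.molecules)
    indices = sorted(range(n), key=lambda i: _molecule_signature(cp.molecules[i]))
    if n == 1:
        return _render(cp, (0,))
    # group consecutive equal signatures; only in-group permutations can alter
    # the rendering, so the search space stays tiny
    groups: list[list[int]] = []
    prev_sig = None
    for i in indices:
        sig = _molecule_signature(cp.molecules[i])
        if sig != prev_sig:
            groups.append([])
            prev_sig = sig
        groups[-1].append(i)
    best: str | None = None
    for perm_parts in itertools.product(*(itertools.permutations(g) for g in groups)):
        order = tuple(itertools.chain.from_iterable(perm_parts))
        s = _render(cp, order)
        if best is None or s < best:
            best = s
    assert best is not None
    return best
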