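"""Independent brute-force oracles used only by the tests.

These are written directly against the pattern dataclasses, without reusing
the package's matching or canonicalization internals, so that each dual-route
check really compares two implementations.
"""

from __future__ import annotations

import itertools

from mpdiag.bngl.model import BondKind, ComplexPattern, MoleculeTypeDef


def _positional_slots(mol, tdef: MoleculeTypeDef) -> list[int]:
    used: set[int] = set()
    slots = []
    for comp in mol.components:
        for ti, cdef in enumerate(tdef.components):
            if cdef.name == comp.name and ti not in used:
                used.add(ti)
                slots.append(ti)
                break
        else:
            raise AssertionError(f"unresolvable component {comp.name}")
    return slots


def species_tables(species_pattern: ComplexPattern, types):
    """Per molecule: slot-indexed states and bond partner (mol, slot)."""
    states = []
    partners = []
    ends: dict[int, list[tuple[int, int]]] = {}
    for mi, mol in enumerate(species_pattern.molecules):
        tdef = types[mol.type_name]
        st: list[str | None] = [None] * len(tdef.components)
        pt: list[tuple[int, int] | None] = [None] * len(tdef.components)
        for comp, slot in zip(mol.components, _positional_slots(mol, tdef)):
            st[slot] = None if comp.state in (None, "?") else comp.state
            if comp.bond.kind is BondKind.LINK:
                ends.setdefault(comp.bond.index, []).append((mi, slot))
        states.append(st)
        partners.append(pt)
    for eps in ends.values():
        (a, sa), (b, sb) = eps
        partners[a][sa] = (b, sb)
        partners[b][sb] = (a, sa)
    return states, partners


def count_embeddings_oracle(pattern: ComplexPattern, species_pattern: ComplexPattern, types) -> int:
    """Count injective embeddings by trying every permutation of target molecules."""
    states, partners = species_tables(species_pattern, types)
    n_s = len(species_pattern.molecules)
    n_p = len(pattern.molecules)
    count = 0
    for perm in itertools.permutations(range(n_s), n_p):
        ok = True
        for pi, si in enumerate(perm):
            pmol = pattern.molecules[pi]
            smol = species_pattern.molecules[si]
            if pmol.type_name != smol.type_name:
                ok = False
                break
            if pmol.compartment is not None and pmol.compartment != smol.compartment:
                ok = False
                break
            tdef = types[pmol.type_name]
            for comp, slot in zip(pmol.components, _positional_slots(pmol, tdef)):
                want_state = None if comp.state in (None, "?") else comp.state
                if want_state is not None and states[si][slot] != want_state:
                    ok = False
                    break
                bonded = partners[si][slot] is not None
                if comp.bond.kind is BondKind.UNBOUND and bonded:
                    ok = False
                    break
                if comp.bond.kind in (BondKind.BOUND_ANY, BondKind.LINK) and not bonded:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        # explicit pattern bonds must land on actual species bonds
        ends: dict[int, list[tuple[int, int]]] = {}
        for pi, pmol in enumerate(pattern.molecules):
            tdef = types[pmol.type_name]
            for comp, slot in zip(pmol.components, _positional_slots(pmol, tdef)):
                if comp.bond.kind is BondKind.LINK:
                    ends.setdefault(comp.bond.index, []).append((pi, slot))
        for eps in ends.values():
            (pa, sa), (pb, sb) = eps
            if partners[perm[pa]][sa] != (perm[pb], sb):
                ok = False
                break
        if ok:
            count += 1
    return count


def patterns_isomorphic_oracle(a: ComplexPattern, b: ComplexPattern) -> bool:
    """Exhaustive bijection search preserving types, constraints and topology."""
    if len(a.molecules) != len(b.molecules):
        return False

    def norm(mol):
        comps = []
        for comp in mol.components:
            state = None if comp.state in (None, "?") else comp.state
            kind = comp.bond.kind
            if state is None and kind is BondKind.ANY:
                # fully unconstrained listed component == omitted component
                if sum(1 for c in mol.components if c.name == comp.name) == 1:
                    continue
            comps.append((comp.name, state, kind))
        return (mol.type_name, mol.compartment, tuple(comps))

    def bond_pairs(cp: ComplexPattern):
        ends: dict[int, list[tuple[int, str, int]]] = {}
        for mi, mol in enumerate(cp.molecules):
            for ci, comp in enumerate(mol.components):
                if comp.bond.kind is BondKind.LINK:
                    occ = sum(1 for c in mol.components[:ci] if c.name == comp.name)
                    ends.setdefault(comp.bond.index, []).append((mi, comp.name, occ))
        return ends

    a_bonds = bond_pairs(a)
    b_bonds = bond_pairs(b)
    for perm in itertools.permutations(range(len(b.molecules))):
        if any(norm(a.molecules[i]) != norm(b.molecules[perm[i]]) for i in range(len(a.molecules))):
            continue
        b_multi = sorted(
            tuple(sorted((mi, name, occ) for mi, name, occ in eps)) for eps in b_bonds.values()
        )
        a_multi = sorted(
            tuple(sorted((perm[mi], name, occ) for mi, name, occ in eps)) for eps in a_bonds.values()
        )
        if a_multi == b_multi:
            return True
    return False
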