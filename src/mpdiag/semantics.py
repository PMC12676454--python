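"""Reactant/product molecule correspondence and per-site classification.

Every reactant-side site of a rule is labeled as one of:

* ``MODIFIED_STATE`` — the state constraint differs between the two sides;
* ``MODIFIED_BOND`` — the bond *class* (any / unbound / bound) differs, or an
  explicit bond partner changes at equal class;
* ``MODIFIED_BOTH`` — both of the above (also all sites of molecules that are
  created or destroyed by the rule);
* ``CONTEXT`` — unchanged, but at least one constraint is not a wildcard (the
  site is required in a specific state/bonding for the rule to apply);
* ``UNCONSTRAINED`` — wildcards on both state and bond (site irrelevant).

Molecules are paired positionally by type name: the leftmost reactant
occurrence of a type pairs with the leftmost product occurrence, and so on;
surplus occurrences are reported as created/destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from mpdiag.bngl.model import (
    ANY_BOND,
    BondKind,
    BondSpec,
    MoleculeTypeDef,
    Rule,
    bond_class,
    resolve_components,
)

__all__ = [
    "MolOcc",
    "SiteRef",
    "MoleculeCorrespondence",
    "SiteLabel",
    "SiteEntry",
    "BondEnd",
    "BondEvent",
    "SiteClassification",
    "map_rule_molecules",
    "classify_sites",
    "classify_rule",
]

REACTANT = "reactant"
PRODUCT = "product"


@dataclass(frozen=True, order=True)
class MolOcc:
    """A molecule occurrence: side, complex-pattern index, molecule index."""

    side: str
    pattern: int
    mol: int


@dataclass(frozen=True, order=True)
class SiteRef:
    """A site occurrence; ``comp`` is the component slot of the molecule type."""

    side: str
    pattern: int
    mol: int
    comp: int

    @property
    def occurrence(self) -> MolOcc:
        return MolOcc(self.side, self.pattern, self.mol)


@dataclass(frozen=True)
class MoleculeCorrespondence:
    rule_id: str
    pairs: tuple[tuple[MolOcc, MolOcc], ...]
    created: tuple[MolOcc, ...]
    destroyed: tuple[MolOcc, ...]
    notes: tuple[str, ...] = ()


class SiteLabel(Enum):
    MODIFIED_STATE = "modified_state"
    MODIFIED_BOND = "modified_bond"
    MODIFIED_BOTH = "modified_both"
    CONTEXT = "context"
    UNCONSTRAINED = "unconstrained"


MODIFIED_LABELS = frozenset(
    {SiteLabel.MODIFIED_STATE, SiteLabel.MODIFIED_BOND, SiteLabel.MODIFIED_BOTH}
)


@dataclass(frozen=True)
class SiteEntry:
    label: SiteLabel
    type_name: str
    comp_name: str
    before_state: str | None = None
    after_state: str | None = None
    before_bond: str | None = None  # bond class: any / unbound / bound
    after_bond: str | None = None
    warnings: tuple[str, ...] = ()

    @property
    def state_changed(self) -> bool:
        return self.before_state != self.after_state

    @property
    def bond_changed(self) -> bool:
        return self.label in (SiteLabel.MODIFIED_BOND, SiteLabel.MODIFIED_BOTH)


@dataclass(frozen=True)
class BondEnd:
    ref: SiteRef
    type_name: str
    comp_name: str


@dataclass(frozen=True)
class BondEvent:
    """An explicit bond formed or broken by the rule (both endpoints known)."""

    a: BondEnd
    b: BondEnd


@dataclass(frozen=True)
class SiteClassification:
    rule_id: str
    entries: dict[SiteRef, SiteEntry]
    formed_bonds: tuple[BondEvent, ...] = ()
    broken_bonds: tuple[BondEvent, ...] = ()
    warnings: tuple[str, ...] = ()

    def reactant_entries(self) -> dict[SiteRef, SiteEntry]:
        return {r: e for r, e in self.entries.items() if r.side == REACTANT}


def _occurrences(rule: Rule, side: str):
    patterns = rule.reactants if side == REACTANT else rule.products
    for pi, cp in enumerate(patterns):
        for mi, mol in enumerate(cp.molecules):
            yield MolOcc(side, pi, mi), mol


def map_rule_molecules(rule: Rule) -> MoleculeCorrespondence:
    """Pair reactant and product molecules by type name, leftmost-first."""
    r_by_type: dict[str, list[MolOcc]] = {}
    p_by_type: dict[str, list[MolOcc]] = {}
    for occ, mol in _occurrences(rule, REACTANT):
        r_by_type.setdefault(mol.type_name, []).append(occ)
    for occ, mol in _occurrences(rule, PRODUCT):
        p_by_type.setdefault(mol.type_name, []).append(occ)
    pairs: list[tuple[MolOcc, MolOcc]] = []
    created: list[MolOcc] = []
    destroyed: list[MolOcc] = []
    notes: list[str] = []
    for tname in list(r_by_type) + [t for t in p_by_type if t not in r_by_type]:
        rs = r_by_type.get(tname, [])
        ps = p_by_type.get(tname, [])
        k = min(len(rs), len(ps))
        pairs.extend(zip(rs[:k], ps[:k]))
        destroyed.extend(rs[k:])
        created.extend(ps[k:])
        if len(rs) > 1 and len(ps) > 1:
            notes.append(
                f"type {tname} occurs {len(rs)}x among reactants and {len(ps)}x among "
                "products; paired positionally leftmost-first"
            )
    pairs.sort()
    return MoleculeCorrespondence(
        rule_id=rule.id,
        pairs=tuple(pairs),
        created=tuple(sorted(created)),
        destroyed=tuple(sorted(destroyed)),
        notes=tuple(notes),
    )


def _site_constraints(mol, tdef: MoleculeTypeDef) -> list[tuple[str | None, BondSpec]]:
    """Per type slot: (state constraint or None, bond constraint).

    Omitted components are fully unconstrained; listed components without a
    bond suffix are constrained to be unbound.
    """
    out: list[tuple[str | None, BondSpec]] = [(None, ANY_BOND)] * len(tdef.components)
    slots = resolve_components(mol, tdef)
    for comp, slot in zip(mol.components, slots):
        out[slot] = (comp.state_value, comp.bond)
    return out


def _partner_map(rule: Rule, side: str, types: Mapping[str, MoleculeTypeDef]) -> dict[SiteRef, SiteRef]:
    """Explicit-bond partner of every LINK endpoint, keyed by SiteRef."""
    patterns = rule.reactants if side == REACTANT else rule.products
    partners: dict[SiteRef, SiteRef] = {}
    for pi, cp in enumerate(patterns):
        refs: dict[int, list[SiteRef]] = {}
        for mi, mol in enumerate(cp.molecules):
            tdef = types[mol.type_name]
            slots = resolve_components(mol, tdef)
            for comp, slot in zip(mol.components, slots):
                if comp.bond.kind is BondKind.LINK:
                    refs.setdefault(comp.bond.index, []).append(SiteRef(side, pi, mi, slot))
        for eps in refs.values():
            a, b = eps
            partners[a] = b
            partners[b] = a
    return partners


def classify_sites(
    rule: Rule,
    corr: MoleculeCorrespondence,
    types: Mapping[str, MoleculeTypeDef],
) -> SiteClassification:
    """Label every reactant-side site of ``rule`` (plus sites of created molecules)."""
    r_mols = dict(_occurrences(rule, REACTANT))
    p_mols = dict(_occurrences(rule, PRODUCT))
    r2p = dict(corr.pairs)
    p2r = {p: r for r, p in corr.pairs}
    r_partner = _partner_map(rule, REACTANT, types)
    p_partner = _partner_map(rule, PRODUCT, types)

    entries: dict[SiteRef, SiteEntry] = {}
    warnings: list[str] = []

    def site_name(tdef: MoleculeTypeDef, slot: int) -> str:
        return tdef.components[slot].name

    for r_occ, p_occ in corr.pairs:
        r_mol, p_mol = r_mols[r_occ], p_mols[p_occ]
        tdef = types[r_mol.type_name]
        rcons = _site_constraints(r_mol, tdef)
        pcons = _site_constraints(p_mol, tdef)
        for slot in range(len(tdef.components)):
            rs, rb = rcons[slot]
            ps, pb = pcons[slot]
            ref = SiteRef(REACTANT, r_occ.pattern, r_occ.mol, slot)
            entry_warnings: list[str] = []
            state_mod = rs != ps
            if state_mod and (rs is None) != (ps is None):
                w = (
                    f"rule {rule.id}: {tdef.name}.{site_name(tdef, slot)} has a wildcard "
                    f"state on one side only ({rs!r} -> {ps!r}); treated as modified"
                )
                entry_warnings.append(w)
                warnings.append(w)
            rcls, pcls = bond_class(rb), bond_class(pb)
            bond_mod = False
            if rcls != pcls:
                bond_mod = True
                if "any" in (rcls, pcls):
                    w = (
                        f"rule {rule.id}: {tdef.name}.{site_name(tdef, slot)} has a wildcard "
                        f"bond on one side only ({rcls} -> {pcls}); treated as modified"
                    )
                    entry_warnings.append(w)
                    warnings.append(w)
            elif rb.kind is BondKind.LINK and pb.kind is BondKind.LINK:
                # equal class "bound" with explicit partners on both sides:
                # a partner identity change still counts as a modification
                rp = r_partner[ref]
                pp = p_partner[SiteRef(PRODUCT, p_occ.pattern, p_occ.mol, slot)]
                mapped = p2r.get(pp.occurrence)
                if mapped is None:
                    bond_mod = True  # rebonded to a freshly created molecule
                elif SiteRef(REACTANT, mapped.pattern, mapped.mol, pp.comp) != rp:
                    bond_mod = True
            if state_mod and bond_mod:
                label = SiteLabel.MODIFIED_BOTH
            elif state_mod:
                label = SiteLabel.MODIFIED_STATE
            elif bond_mod:
                label = SiteLabel.MODIFIED_BOND
            elif rs is not None or rcls != "any":
                label = SiteLabel.CONTEXT
            else:
                label = SiteLabel.UNCONSTRAINED
            entries[ref] = SiteEntry(
                label=label,
                type_name=tdef.name,
                comp_name=site_name(tdef, slot),
                before_state=rs,
                after_state=ps if state_mod else rs,
                before_bond=rcls,
                after_bond=pcls,
                warnings=tuple(entry_warnings),
            )

    for occ in corr.destroyed:
        mol = r_mols[occ]
        tdef = types[mol.type_name]
        rcons = _site_constraints(mol, tdef)
        for slot in range(len(tdef.components)):
            rs, rb = rcons[slot]
            entries[SiteRef(REACTANT, occ.pattern, occ.mol, slot)] = SiteEntry(
                label=SiteLabel.MODIFIED_BOTH,
                type_name=tdef.name,
                comp_name=site_name(tdef, slot),
                before_state=rs,
                after_state=None,
                before_bond=bond_class(rb),
                after_bond=None,
            )
    for occ in corr.created:
        mol = p_mols[occ]
        tdef = types[mol.type_name]
        pcons = _site_constraints(mol, tdef)
        for slot in range(len(tdef.components)):
            ps, pb = pcons[slot]
            entries[SiteRef(PRODUCT, occ.pattern, occ.mol, slot)] = SiteEntry(
                label=SiteLabel.MODIFIED_BOTH,
                type_name=tdef.name,
                comp_name=site_name(tdef, slot),
                before_state=None,
                after_state=ps,
                before_bond=None,
                after_bond=bond_class(pb),
            )

    # explicit bond formation / breakage events (both endpoints known)
    def _end(ref: SiteRef) -> BondEnd:
        mols = r_mols if ref.side == REACTANT else p_mols
        tdef = types[mols[ref.occurrence].type_name]
        return BondEnd(ref=ref, type_name=tdef.name, comp_name=tdef.components[ref.comp].name)

    def _map_back(ref: SiteRef) -> SiteRef | None:
        mapped = p2r.get(ref.occurrence)
        if mapped is None:
            return None
        return SiteRef(REACTANT, mapped.pattern, mapped.mol, ref.comp)

    def _map_fwd(ref: SiteRef) -> SiteRef | None:
        mapped = r2p.get(ref.occurrence)
        if mapped is None:
            return None
        return SiteRef(PRODUCT, mapped.pattern, mapped.mol, ref.comp)

    formed: list[BondEvent] = []
    seen_p: set[SiteRef] = set()
    for a, b in p_partner.items():
        if a in seen_p or b in seen_p:
            continue
        seen_p.update((a, b))
        ra, rb_ = _map_back(a), _map_back(b)
        if ra is not None and rb_ is not None and r_partner.get(ra) == rb_:
            continue  # unchanged context bond
        ea = _end(ra) if ra is not None else _end(a)
        eb = _end(rb_) if rb_ is not None else _end(b)
        formed.append(BondEvent(*sorted((ea, eb), key=lambda e: (e.type_name, e.comp_name, e.ref))))
    broken: list[BondEvent] = []
    seen_r: set[SiteRef] = set()
    for a, b in r_partner.items():
        if a in seen_r or b in seen_r:
            continue
        seen_r.update((a, b))
        pa, pb_ = _map_fwd(a), _map_fwd(b)
        if pa is not None and pb_ is not None and p_partner.get(pa) == pb_:
            continue
        broken.append(
            BondEvent(*sorted((_end(a), _end(b)), key=lambda e: (e.type_name, e.comp_name, e.ref)))
        )

    return SiteClassification(
        rule_id=rule.id,
        entries=entries,
        formed_bonds=tuple(formed),
        broken_bonds=tuple(broken),
        warnings=tuple(warnings),
    )


def classify_rule(rule: Rule, types: Mapping[str, MoleculeTypeDef]):
    """Convenience: correspondence plus classification in one call."""
    corr = map_rule_molecules(rule)
    return corr, classify_sites(rule, corr, types)
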