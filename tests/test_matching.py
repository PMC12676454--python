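import random

import pytest

from mpdiag import GeneratorConfig, random_model
from mpdiag.bngl import parse_complex_pattern, parse_model
from mpdiag.bngl.model import ComponentDef, MoleculeTypeDef
from mpdiag.errors import ExpansionOverflowError, UnsupportedRuleError
from mpdiag.matching import (
    ConcreteSpecies,
    apply_rule,
    enumerate_states,
    expand_rule,
    iter_state_combinations,
    match,
)

from tests.oracles import count_embeddings_oracle


def _species(text, types):
    return ConcreteSpecies.from_pattern(parse_complex_pattern(text), types)


@pytest.fixture(scope="module")
def egfr_types(egfr):
    return egfr.types_by_name()


@pytest.fixture(scope="module")
def egfr_seeds(egfr, egfr_types):
    return [ConcreteSpecies.from_pattern(cp, egfr_types) for cp, _ in egfr.seed_species]


class TestMatch:
    def test_unbound_requirement_blocks_bound_site(self, egfr_types):
        pattern = parse_complex_pattern("EGFR(ecd)")
        species = _species("EGF(site!1).EGFR(ecd!1,tmd,Y1~U,Y2~U)", egfr_types)
        assert match(pattern, species, egfr_types) == []

    def test_wildcard_state_matches(self, egfr_types):
        pattern = parse_complex_pattern("EGFR(Y1~?)")
        species = _species("EGFR(ecd,tmd,Y1~P,Y2~U)", egfr_types)
        assert len(match(pattern, species, egfr_types)) == 1

    def test_bound_any_requires_bond(self, egfr_types):
        pattern = parse_complex_pattern("EGFR(ecd!+)")
        free = _species("EGFR(ecd,tmd,Y1~U,Y2~U)", egfr_types)
        bound = _species("EGF(site!1).EGFR(ecd!1,tmd,Y1~U,Y2~U)", egfr_types)
        assert match(pattern, free, egfr_types) == []
        assert len(match(pattern, bound, egfr_types)) == 1

    def test_explicit_bond_topology_respected(self, egfr_types):
        pattern = parse_complex_pattern("EGF(site!1).EGFR(ecd!1)")
        species = _species("EGF(site!1).EGFR(ecd!1,tmd,Y1~U,Y2~U)", egfr_types)
        assert len(match(pattern, species, egfr_types)) == 1

    def test_dimer_pattern_two_automorphic_embeddings(self, egfr_types):
        pattern = parse_complex_pattern("EGFR(tmd!1).EGFR(tmd!1)")
        species = _species(
            "EGFR(ecd,tmd!1,Y1~U,Y2~U).EGFR(ecd,tmd!1,Y1~U,Y2~U)", egfr_types
        )
        assert len(match(pattern, species, egfr_types)) == 2

    def test_counts_match_brute_force_oracle_on_corpus(self, corpus):
        """Dual-route check: package matcher vs independent permutation search."""
        rng = random.Random(99)
        checked = 0
        for model in corpus[:30]:
            types = model.types_by_name()
            species = _random_species(model, rng)
            if species is None:
                continue
            for rule in model.rules:
                for pattern in rule.reactants:
                    ours = len(match(pattern, species, types))
                    oracle = count_embeddings_oracle(pattern, species.pattern, types)
                    assert ours == oracle
                    checked += 1
        assert checked > 50


def _random_species(model, rng):
    """Grow a connected concrete species from the model's types (test helper)."""
    types = model.types_by_name()
    mols = []
    bonds = []  # (mol_index, slot, mol_index, slot)
    free = []
    for i in range(rng.randint(1, 3)):
        tdef = rng.choice(model.molecule_types)
        states = [rng.choice(c.states) if c.states else None for c in tdef.components]
        mols.append((tdef, states))
        for slot in range(len(tdef.components)):
            free.append((i, slot))
    # connect molecules 1..n-1 to earlier ones through free sites
    for i in range(1, len(mols)):
        anchors = [(m, s) for m, s in free if m < i]
        mine = [(m, s) for m, s in free if m == i]
        if not anchors or not mine:
            return None
        a = rng.choice(anchors)
        b = rng.choice(mine)
        free.remove(a)
        free.remove(b)
        bonds.append((a, b))
    parts = []
    bond_idx = {}
    for n, (pair) in enumerate(bonds, start=1):
        for end in pair:
            bond_idx[end] = n
    for i, (tdef, states) in enumerate(mols):
        comps = []
        for slot, cdef in enumerate(tdef.components):
            token = cdef.name
            if states[slot] is not None:
                token += f"~{states[slot]}"
            if (i, slot) in bond_idx:
                token += f"!{bond_idx[(i, slot)]}"
            comps.append(token)
        parts.append(f"{tdef.name}({','.join(comps)})")
    return ConcreteSpecies.from_pattern(parse_complex_pattern(".".join(parts)), types)


class TestExpand:
    def test_binding_rule_four_reactions(self, egfr, egfr_seeds):
        result = expand_rule(egfr, egfr.rule_by_id("R1"), egfr_seeds, max_iterations=1)
        assert len(result.reactions) == 4
        assert not result.fixed_point  # new complexes were produced but not re-expanded

    def test_single_seed_single_reaction(self, egfr, egfr_types):
        seeds = [
            _species("EGF(site)", egfr_types),
            _species("EGFR(ecd,tmd,Y1~U,Y2~U)", egfr_types),
        ]
        result = expand_rule(egfr, egfr.rule_by_id("R1"), seeds, max_iterations=1)
        assert len(result.reactions) == 1

    def test_transphosphorylation_on_dimers(self, egfr, egfr_types):
        """Reaction count equals the distinct-outcome count from the oracle."""
        dimers = []
        for y1a in "UP":
            for y1b in "UP":
                dimers.append(
                    _species(
                        f"EGFR(ecd,tmd!1,Y1~{y1a},Y2~U).EGFR(ecd,tmd!1,Y1~{y1b},Y2~U)",
                        egfr_types,
                    )
                )
        rule = egfr.rule_by_id("R5")
        result = expand_rule(egfr, rule, dimers, max_iterations=1)
        # distinct seeds: UU (isomorphic collapse), UP == PU, PP; applicable: UU, UP
        # UU -> PU; UP -> PP: two distinct reactions
        assert len(result.reactions) == 2
        # embeddings: UU has 2 automorphic embeddings collapsing to 1 reaction
        embeddings = sum(len(match(rule.reactants[0], d, egfr_types)) for d in dimers)
        assert embeddings == 4  # 2 (UU) + 1 (UP) + 1 (PU) + 0 (PP)

    def test_fixed_point_reached(self, egfr, egfr_seeds):
        result = expand_rule(egfr, egfr.rule_by_id("R1"), egfr_seeds, max_iterations=5)
        assert result.fixed_point
        assert len(result.reactions) == 4  # binding saturates after one round

    def test_invariant_to_seed_order_and_bond_labels(self, egfr, egfr_types):
        seeds_a = [
            _species("EGF(site)", egfr_types),
            _species("EGFR(ecd,tmd,Y1~U,Y2~P)", egfr_types),
            _species("EGFR(ecd,tmd,Y1~P,Y2~P)", egfr_types),
        ]
        seeds_b = list(reversed(seeds_a))
        ra = expand_rule(egfr, egfr.rule_by_id("R1"), seeds_a)
        rb = expand_rule(egfr, egfr.rule_by_id("R1"), seeds_b)
        key = lambda r: (r.reactants, r.products)
        assert sorted(map(key, ra.reactions)) == sorted(map(key, rb.reactions))

    def test_unbinding_splits_products(self):
        model = parse_model(
            "begin molecule types\nA(x)\nB(y)\nend molecule types\n"
            "begin reaction rules\nA(x!1).B(y!1) -> A(x) + B(y) k\nend reaction rules\n"
        )
        types = model.types_by_name()
        seed = _species("A(x!1).B(y!1)", types)
        result = expand_rule(model, model.rules[0], [seed])
        (rxn,) = result.reactions
        assert rxn.products == ("A(x)", "B(y)")

    def test_degradation_and_synthesis(self):
        model = parse_model(
            "begin molecule types\nA(x)\nend molecule types\n"
            "begin reaction rules\nA() -> 0 k\n0 -> A(x) k\nend reaction rules\n"
        )
        types = model.types_by_name()
        seed = _species("A(x)", types)
        deg = expand_rule(model, model.rules[0], [seed])
        (rxn,) = deg.reactions
        assert rxn.products == ()
        syn = expand_rule(model, model.rules[1], [])
        (rxn,) = syn.reactions
        assert rxn.reactants == () and rxn.products == ("A(x)",)

    def test_wildcard_product_unsupported(self):
        model = parse_model(
            "begin molecule types\nA(x~U~P)\nend molecule types\n"
            "begin reaction rules\n0 -> A(x~?) k\nend reaction rules\n"
        )
        with pytest.raises(UnsupportedRuleError):
            expand_rule(model, model.rules[0], [])

    def test_species_cap_overflow_is_explicit(self):
        model = parse_model(
            "begin molecule types\nA(h,t)\nend molecule types\n"
            "begin reaction rules\nA(h) + A(t) -> A(h!1).A(t!1) k\nend reaction rules\n"
        )
        types = model.types_by_name()
        seed = _species("A(h,t)", types)
        with pytest.raises(ExpansionOverflowError):
            expand_rule(model, model.rules[0], [seed], max_iterations=50, species_cap=10)


class TestExpansionConsistency:
    """Concrete site diffs must equal the MODIFIED classification under embedding."""

    def _diff(self, before, after):
        changed = set()
        for mid in set(before) | set(after):
            if mid not in before or mid not in after:
                bmol = before.get(mid) or after[mid]
                changed.update((mid, slot) for slot in range(len(bmol.states)))
                continue
            b, a = before[mid], after[mid]
            for slot in range(len(b.states)):
                if b.states[slot] != a.states[slot] or b.bonds[slot] != a.bonds[slot]:
                    changed.add((mid, slot))
        return changed

    def _expected(self, model, rule, embeddings, species_list):
        from mpdiag.semantics import REACTANT, MODIFIED_LABELS, classify_rule

        types = model.types_by_name()
        corr, cls = classify_rule(rule, types)
        offsets = []
        total = 0
        for sp in species_list:
            offsets.append(total)
            total += len(sp.pattern.molecules)
        expected = set()
        for ref, entry in cls.entries.items():
            if entry.label not in MODIFIED_LABELS:
                continue
            if ref.side == REACTANT:
                mid = offsets[ref.pattern] + embeddings[ref.pattern][ref.mol]
                expected.add((mid, ref.comp))
        # created molecules get sequential ids after all reactant instances,
        # in correspondence order; every site of a created molecule changes
        for i, occ in enumerate(corr.created):
            mol = rule.products[occ.pattern].molecules[occ.mol]
            n_slots = len(types[mol.type_name].components)
            expected.update((total + i, slot) for slot in range(n_slots))
        return expected

    def test_fixture_rules(self, egfr, egfr_types, egfr_seeds):
        ra = _species("EGF(site!1).EGFR(ecd!1,tmd,Y1~U,Y2~U)", egfr_types)
        dimer = _species(
            "EGFR(ecd,tmd!1,Y1~U,Y2~P).EGFR(ecd,tmd!1,Y1~U,Y2~U)", egfr_types
        )
        pools = {
            "R1": egfr_seeds,
            "R2": [_species("EGFR(ecd,tmd,Y1~P,Y2~U)", egfr_types)],
            "R3": [_species("EGFR(ecd,tmd,Y1~U,Y2~P)", egfr_types)],
            "R4": [ra],
            "R5": [dimer],
            "R6": [dimer],
        }
        checked = 0
        for rid, seeds in pools.items():
            rule = egfr.rule_by_id(rid)
            types = egfr_types
            import itertools

            for combo in itertools.product(seeds, repeat=len(rule.reactants)):
                per = [match(p, s, types) for p, s in zip(rule.reactants, combo)]
                if any(not e for e in per):
                    continue
                for embset in itertools.product(*per):
                    result = apply_rule(egfr, rule, combo, embset)
                    observed = self._diff(result.before, result.after)
                    expected = self._expected(egfr, rule, embset, combo)
                    assert observed == expected, (rid, combo)
                    checked += 1
        assert checked >= 6

    def test_random_state_rules(self, corpus):
        """Same check across every expandable random rule with groundable reactants."""
        import itertools

        from mpdiag.bngl.model import BondKind

        rng = random.Random(5)
        checked = 0
        for model in corpus:
            types = model.types_by_name()
            for rule in model.rules:
                seeds = []
                groundable = True
                for cp in rule.reactants:
                    sp = _ground(cp, types, rng)
                    if sp is None:
                        groundable = False
                        break
                    seeds.append(sp)
                if not groundable:
                    continue
                try:
                    per = [match(p, s, types) for p, s in zip(rule.reactants, seeds)]
                except Exception:
                    continue
                if any(not e for e in per):
                    continue
                for embset in itertools.product(*per):
                    try:
                        result = apply_rule(model, rule, seeds, embset)
                    except UnsupportedRuleError:
                        break
                    observed = self._diff(result.before, result.after)
                    expected = self._expected(model, rule, embset, seeds)
                    assert observed == expected, (model.name, rule.id)
                    checked += 1
        assert checked > 40


def _ground(cp, types, rng):
    """Instantiate a pattern as a concrete species when no '!+' context blocks it."""
    from mpdiag.bngl.model import BondKind

    parts = []
    for mol in cp.molecules:
        tdef = types[mol.type_name]
        listed = {}
        from mpdiag.bngl.model import resolve_components

        for comp, slot in zip(mol.components, resolve_components(mol, tdef)):
            if comp.bond.kind is BondKind.BOUND_ANY:
                return None  # would need an unspecified partner
            listed[slot] = comp
        comps = []
        for slot, cdef in enumerate(tdef.components):
            comp = listed.get(slot)
            token = cdef.name
            if comp is not None and comp.state_value is not None:
                token += f"~{comp.state_value}"
            elif cdef.states:
                token += f"~{cdef.states[0]}"
            if comp is not None and comp.bond.kind is BondKind.LINK:
                token += f"!{comp.bond.index}"
            comps.append(token)
        parts.append(f"{mol.type_name}({','.join(comps)})")
    try:
        return ConcreteSpecies.from_pattern(parse_complex_pattern(".".join(parts)), types)
    except Exception:
        return None


class TestEnumerateStates:
    def test_nine_two_state_components(self):
        mt = MoleculeTypeDef(
            "R", tuple(ComponentDef(f"y{i}", ("U", "P")) for i in range(9))
        )
        assert enumerate_states(mt) == 512

    def test_stateless_molecule(self):
        mt = MoleculeTypeDef("L", (ComponentDef("site"),))
        assert enumerate_states(mt) == 1

    def test_fixture_receptor(self, egfr_types):
        assert enumerate_states(egfr_types["EGFR"]) == 4  # 2 x 2 tyrosine states

    def test_listing_matches_count(self, egfr_types):
        mt = egfr_types["EGFR"]
        listing = list(iter_state_combinations(mt))
        assert len(listing) == enumerate_states(mt)
        assert len(set(listing)) == len(listing)
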