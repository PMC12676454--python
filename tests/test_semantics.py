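import pytest

from mpdiag.bngl import parse_model
from mpdiag.semantics import (
    PRODUCT,
    REACTANT,
    SiteLabel,
    classify_rule,
    classify_sites,
    map_rule_molecules,
)


def _entry(cls, type_name, comp_name, side=REACTANT):
    found = [
        e
        for ref, e in cls.entries.items()
        if ref.side == side and e.type_name == type_name and e.comp_name == comp_name
    ]
    assert len(found) >= 1
    return found


def _labels(cls, type_name, comp_name, side=REACTANT):
    return {e.label for e in _entry(cls, type_name, comp_name, side)}


class TestCorrespondence:
    def test_binding_rule_pairs_both_molecules(self, egfr):
        corr = map_rule_molecules(egfr.rule_by_id("R1"))
        assert len(corr.pairs) == 2
        assert corr.created == ()
        assert corr.destroyed == ()
        for r_occ, p_occ in corr.pairs:
            assert r_occ.side == REACTANT and p_occ.side == PRODUCT

    def test_degradation_reports_destroyed(self):
        model = parse_model(
            "begin molecule types\nA(x)\nend molecule types\n"
            "begin reaction rules\nA(x) -> 0 k\nend reaction rules\n"
        )
        corr = map_rule_molecules(model.rules[0])
        assert corr.pairs == ()
        assert len(corr.destroyed) == 1

    def test_synthesis_reports_created(self):
        model = parse_model(
            "begin molecule types\nA(x)\nend molecule types\n"
            "begin reaction rules\n0 -> A(x) k\nend reaction rules\n"
        )
        corr = map_rule_molecules(model.rules[0])
        assert len(corr.created) == 1

    def test_ambiguous_multiplicity_noted(self, egfr):
        corr = map_rule_molecules(egfr.rule_by_id("R4"))
        assert corr.notes  # two EGFR on both sides -> provenance note


class TestClassification:
    def test_binding_rule_fig_semantics(self, egfr):
        _, cls = classify_rule(egfr.rule_by_id("R1"), egfr.types_by_name())
        assert _labels(cls, "EGF", "site") == {SiteLabel.MODIFIED_BOND}
        assert _labels(cls, "EGFR", "ecd") == {SiteLabel.MODIFIED_BOND}
        assert _labels(cls, "EGFR", "tmd") == {SiteLabel.CONTEXT}
        assert _labels(cls, "EGFR", "Y1") == {SiteLabel.UNCONSTRAINED}
        assert _labels(cls, "EGFR", "Y2") == {SiteLabel.UNCONSTRAINED}
        (site_entry,) = _entry(cls, "EGF", "site")
        assert (site_entry.before_bond, site_entry.after_bond) == ("unbound", "bound")

    def test_dimerization_context_vs_modified(self, egfr):
        _, cls = classify_rule(egfr.rule_by_id("R4"), egfr.types_by_name())
        assert _labels(cls, "EGFR", "ecd") == {SiteLabel.CONTEXT}
        assert _labels(cls, "EGFR", "tmd") == {SiteLabel.MODIFIED_BOND}

    def test_transphosphorylation(self, egfr):
        _, cls = classify_rule(egfr.rule_by_id("R5"), egfr.types_by_name())
        labels = _labels(cls, "EGFR", "Y1")
        assert labels == {SiteLabel.MODIFIED_STATE, SiteLabel.UNCONSTRAINED}
        assert _labels(cls, "EGFR", "tmd") == {SiteLabel.CONTEXT}
        modified = [
            e for e in _entry(cls, "EGFR", "Y1") if e.label is SiteLabel.MODIFIED_STATE
        ]
        assert (modified[0].before_state, modified[0].after_state) == ("U", "P")

    def test_identity_rule_has_zero_modified_sites(self):
        model = parse_model(
            "begin molecule types\nA(x~U~P)\nend molecule types\n"
            "begin reaction rules\nA(x~U) -> A(x~U) k\nend reaction rules\n"
        )
        _, cls = classify_rule(model.rules[0], model.types_by_name())
        assert all(
            e.label in (SiteLabel.CONTEXT, SiteLabel.UNCONSTRAINED)
            for e in cls.entries.values()
        )

    def test_destroyed_molecule_sites_all_modified_both(self):
        model = parse_model(
            "begin molecule types\nA(x,y~U~P)\nend molecule types\n"
            "begin reaction rules\nA(x) -> 0 k\nend reaction rules\n"
        )
        _, cls = classify_rule(model.rules[0], model.types_by_name())
        assert {e.label for e in cls.entries.values()} == {SiteLabel.MODIFIED_BOTH}
        assert len(cls.entries) == 2  # every site of the type, listed or not

    def test_wildcard_to_concrete_warns(self):
        model = parse_model(
            "begin molecule types\nA(x~U~P)\nend molecule types\n"
            "begin reaction rules\nA() -> A(x~P!?) k\nend reaction rules\n"
        )
        _, cls = classify_rule(model.rules[0], model.types_by_name())
        assert cls.warnings  # never silent
        assert _labels(cls, "A", "x") == {SiteLabel.MODIFIED_STATE}

    def test_wildcard_to_concrete_bond_and_state_warns(self):
        model = parse_model(
            "begin molecule types\nA(x~U~P)\nend molecule types\n"
            "begin reaction rules\nA() -> A(x~P) k\nend reaction rules\n"
        )
        _, cls = classify_rule(model.rules[0], model.types_by_name())
        assert cls.warnings
        # product also pins the bond (listed without '!' means unbound)
        assert _labels(cls, "A", "x") == {SiteLabel.MODIFIED_BOTH}

    def test_any_bond_both_sides_is_not_modified(self):
        model = parse_model(
            "begin molecule types\nA(x,y~U~P)\nend molecule types\n"
            "begin reaction rules\nA(x!?,y~U) -> A(x!?,y~P) k\nend reaction rules\n"
        )
        _, cls = classify_rule(model.rules[0], model.types_by_name())
        assert _labels(cls, "A", "x") == {SiteLabel.UNCONSTRAINED}

    def test_partner_change_at_equal_bond_class_is_modified(self):
        model = parse_model(
            "begin molecule types\nA(x)\nB(y)\nC(z)\nend molecule types\n"
            "begin reaction rules\n"
            "A(x!1).B(y!1) + C(z) -> A(x!1).C(z!1) + B(y) k\n"
            "end reaction rules\n"
        )
        _, cls = classify_rule(model.rules[0], model.types_by_name())
        assert _labels(cls, "A", "x") == {SiteLabel.MODIFIED_BOND}
        assert _labels(cls, "B", "y") == {SiteLabel.MODIFIED_BOND}
        assert _labels(cls, "C", "z") == {SiteLabel.MODIFIED_BOND}

    def test_bound_any_released_is_modified(self):
        model = parse_model(
            "begin molecule types\nA(x)\nend molecule types\n"
            "begin reaction rules\nA(x!+) -> A(x) k\nend reaction rules\n"
        )
        _, cls = classify_rule(model.rules[0], model.types_by_name())
        assert _labels(cls, "A", "x") == {SiteLabel.MODIFIED_BOND}


class TestProperties:
    def test_partition_covers_all_reactant_sites(self, corpus):
        for model in corpus:
            types = model.types_by_name()
            for rule in model.rules:
                _, cls = classify_rule(rule, types)
                expected = sum(
                    len(types[mol.type_name].components)
                    for cp in rule.reactants
                    for mol in cp.molecules
                )
                reactant_entries = cls.reactant_entries()
                assert len(reactant_entries) == expected

    def test_reversal_symmetry(self, corpus, egfr):
        models = corpus[:30] + [egfr]
        for model in models:
            types = model.types_by_name()
            for rule in model.rules:
                _, fwd = classify_rule(rule, types)
                _, rev = classify_rule(rule.reversed(), types)
                fwd_counts = _label_histogram(fwd)
                rev_counts = _label_histogram(rev)
                # context/unconstrained counts are direction-independent
                assert fwd_counts[SiteLabel.CONTEXT] == rev_counts[SiteLabel.CONTEXT]
                assert (
                    fwd_counts[SiteLabel.UNCONSTRAINED]
                    == rev_counts[SiteLabel.UNCONSTRAINED]
                )
                # modified records mirror before/after
                def records(cls, mirrored):
                    out = []
                    for e in cls.entries.values():
                        if e.label in (SiteLabel.CONTEXT, SiteLabel.UNCONSTRAINED):
                            continue
                        rec = (e.before_state, e.after_state, e.before_bond, e.after_bond)
                        if mirrored:
                            rec = (rec[1], rec[0], rec[3], rec[2])
                        out.append(tuple("" if v is None else v for v in rec))
                    return sorted(out)

                assert records(fwd, False) == records(rev, True)


def _label_histogram(cls):
    out = {label: 0 for label in SiteLabel}
    for e in cls.entries.values():
        out[e.label] += 1
    return out
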