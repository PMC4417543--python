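"""Template engine: pattern grammar, catalogue loading, binding
validation and candidate instantiation."""

from __future__ import annotations

import pytest

from termforge.errors import BindingError, PatternError, TemplateConfigError
from termforge.expressions import Existential, LabelRef, Named, Variable
from termforge.fixtures import CAMPTOTHECIN
from termforge.templates import (
    Binding,
    instantiate,
    load_template_config,
    parse_pattern,
    validate_binding,
)

RELATIONS = {
    "exports": "exports",
    "part_of": "part_of",
    "transports or maintains localization of":
        "transports_or_maintains_localization_of",
    "has target start location": "has_target_start_location",
    "has target end location": "has_target_end_location",
}


class TestParsePattern:
    def test_genus_plus_existential(self):
        p = parse_pattern("GO:0006810 and 'exports' some ?X", RELATIONS)
        assert [c.expr for c in p.conjuncts] == [
            Named("GO:0006810"), Existential("exports", Variable("X"))]
        assert all(c.optional_for is None for c in p.conjuncts)

    def test_optional_bracketed_conjunct(self):
        p = parse_pattern(
            "GO:0006810 and 'transports or maintains localization of' some ?X "
            "[and 'has target start location' some ?F]",
            RELATIONS,
        )
        assert p.conjuncts[2].optional_for == "F"
        assert p.conjuncts[2].expr == Existential(
            "has_target_start_location", Variable("F"))

    def test_variable_genus(self):
        p = parse_pattern("?P and 'part_of' some ?W", RELATIONS)
        assert p.conjuncts[0].expr == Variable("P")
        assert p.conjuncts[1].expr == Existential("part_of", Variable("W"))

    def test_label_genus_and_curie_filler(self):
        p = parse_pattern("'transport' and 'part_of' some GO:0008150",
                          RELATIONS)
        assert p.conjuncts[0].expr == LabelRef("transport")
        assert p.conjuncts[1].expr == Existential("part_of",
                                                  Named("GO:0008150"))

    def test_unknown_relation_label_rejected(self):
        with pytest.raises(PatternError, match="unknown relation"):
            parse_pattern("GO:0006810 and 'no such rel' some ?X", RELATIONS)

    def test_grammar_violation_rejected(self):
        with pytest.raises(PatternError):
            parse_pattern("GO:0006810 'exports' some ?X", RELATIONS)


class TestCatalogue:
    def test_every_template_loads_and_is_well_formed(self, catalogue):
        assert catalogue.templates, "catalogue must not be empty"
        names = [t.name for t in catalogue.templates]
        assert len(names) == len(set(names))
        for t in catalogue.templates:
            n_class = len(t.class_fields())
            assert 1 <= n_class <= 3
            for f in t.class_fields():
                assert f.subset_roots
            assert t.pattern.variables() <= {f.name for f in t.fields}

    def test_chemical_export_template_shape(self, catalogue):
        t = catalogue.by_name("chemical_export")
        (x,) = t.class_fields()
        assert x.subset_roots == ("CHEBI:24431",)
        assert t.pattern.conjuncts[0].expr == Named("GO:0006810")

    def test_subset_roots_resolve_in_mini_ontology(self, catalogue, mini_ont):
        for t in catalogue.templates:
            for f in t.class_fields():
                for root in f.subset_roots:
                    assert root in mini_ont.terms, (t.name, root)

    def test_undeclared_variable_rejected(self):
        cfg = {
            "relations": {"exports": "exports"},
            "subsets": {"chebi": ["CHEBI:24431"]},
            "templates": [{
                "name": "broken",
                "fields": [{"name": "X", "kind": "class", "subsets": ["chebi"]}],
                "pattern": "GO:0006810 and 'exports' some ?Y",
            }],
        }
        with pytest.raises(TemplateConfigError, match="not declared"):
            load_template_config(cfg)

    def test_duplicate_template_name_rejected(self, catalogue):
        entry = {
            "name": "twice",
            "fields": [{"name": "X", "kind": "class", "subsets": ["chebi"]}],
            "pattern": "GO:0006810 and 'exports' some ?X",
        }
        cfg = {"relations": {"exports": "exports"},
               "subsets": {"chebi": ["CHEBI:24431"]},
               "templates": [entry, dict(entry)]}
        with pytest.raises(TemplateConfigError, match="duplicate template"):
            load_template_config(cfg)

    def test_empty_config_yields_no_templates(self):
        assert load_template_config("").templates == []


class TestValidateBinding:
    def test_valid_chebi_binding_passes(self, catalogue, mini_ont):
        t = catalogue.by_name("chemical_export")
        failures = validate_binding(
            t, Binding(values={"X": CAMPTOTHECIN}, references=("PMID:1",)),
            mini_ont)
        assert failures == []

    def test_missing_literature_reference_is_named(self, catalogue, mini_ont):
        t = catalogue.by_name("chemical_export")
        failures = validate_binding(
            t, Binding(values={"X": CAMPTOTHECIN}), mini_ont)
        assert [f.field for f in failures] == ["ref"]

    def test_subset_violation_detected(self, catalogue, mini_ont):
        # a BP process class bound to a ChEBI-rooted field
        t = catalogue.by_name("chemical_export")
        failures = validate_binding(
            t, Binding(values={"X": "GO:0008152"}, references=("PMID:1",)),
            mini_ont)
        assert any("subset" in f.message for f in failures)

    def test_missing_required_field_detected(self, catalogue, mini_ont):
        t = catalogue.by_name("chemical_export")
        failures = validate_binding(
            t, Binding(values={}, references=("PMID:1",)), mini_ont)
        assert any(f.field == "X" and "required" in f.message
                   for f in failures)

    def test_malformed_reference_detected(self, catalogue, mini_ont):
        t = catalogue.by_name("chemical_export")
        failures = validate_binding(
            t, Binding(values={"X": CAMPTOTHECIN}, references=("not a ref",)),
            mini_ont)
        assert any(f.field == "ref" for f in failures)


class TestInstantiate:
    def test_regulation_label(self, catalogue, mini_ont):
        t = catalogue.by_name("regulation_bp")
        cand = instantiate(
            t, Binding(values={"X": "TEST:0000101"}, references=("PMID:1",)),
            mini_ont)
        assert cand.label == "regulation of cell migration"

    def test_chemical_export_logical_definition(self, catalogue, mini_ont):
        t = catalogue.by_name("chemical_export")
        cand = instantiate(
            t, Binding(values={"X": CAMPTOTHECIN}, references=("PMID:1",)),
            mini_ont)
        from termforge.expressions import Conjunction
        assert cand.logical_def == Conjunction(
            (Named("GO:0006810"), Existential("exports", Named(CAMPTOTHECIN))))
        assert cand.def_xrefs == ("PMID:1",)

    def test_synonym_rule_applies_to_each_exact_synonym(self, catalogue,
                                                        mini_ont):
        t = catalogue.by_name("catabolism")
        cand = instantiate(
            t, Binding(values={"X": "CHEBI:22315"}, references=("PMID:1",)),
            mini_ont)
        # 'alkaloid' has the EXACT synonym 'alkaloids'; both rules fire
        assert ("alkaloids catabolism", "EXACT") in cand.synonyms
        assert ("alkaloids breakdown", "EXACT") in cand.synonyms

    def test_optional_conjunct_dropped_when_unbound(self, catalogue, mini_ont):
        t = catalogue.by_name("chemical_transport_from_to")
        cand = instantiate(
            t, Binding(values={"X": "TEST:0000301", "T": "TEST:0000202"},
                       references=("PMID:1",)),
            mini_ont)
        assert cand.label == "glucose transport to vacuole"
        props = {p.prop for p in cand.logical_def.parts
                 if isinstance(p, Existential)}
        assert "has_target_start_location" not in props
        assert "has_target_end_location" in props

    def test_instantiation_is_deterministic(self, catalogue, mini_ont):
        t = catalogue.by_name("catabolism")
        b = Binding(values={"X": CAMPTOTHECIN}, references=("PMID:1",))
        assert instantiate(t, b, mini_ont) == instantiate(t, b, mini_ont)

    def test_invalid_binding_raises(self, catalogue, mini_ont):
        t = catalogue.by_name("chemical_export")
        with pytest.raises(BindingError):
            instantiate(t, Binding(values={"X": "GO:0008152"},
                                   references=("PMID:1",)), mini_ont)
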