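"""Ontology model and OBO reader/writer."""

from __future__ import annotations

import io

import pytest

from termforge.errors import (
    DuplicateIdError,
    OboLoadWarning,
    OboParseError,
    TermforgeError,
    UnknownClassError,
)
from termforge.expressions import (
    Conjunction,
    Existential,
    Named,
    conjunction_of,
)
from termforge.fixtures import RandomOntologySpec, random_ontology
from termforge.obo import (
    TermRecord,
    apply_new_term,
    obsolete_term,
    parse_obo,
    write_obo,
)

HEADER = "format-version: 1.4\nontology: test\n\n"


class TestExpressions:
    def test_conjunction_is_flattened_and_order_insensitive(self):
        a = Conjunction((Named("A:1"), Existential("r", Named("B:1"))))
        b = Conjunction((Existential("r", Named("B:1")), Named("A:1")))
        assert a == b
        nested = Conjunction((Named("C:1"), a))
        assert nested == Conjunction(
            (Named("A:1"), Named("C:1"), Existential("r", Named("B:1")))
        )

    def test_conjunction_needs_two_distinct_parts(self):
        with pytest.raises(ValueError):
            Conjunction((Named("A:1"), Named("A:1")))
        assert conjunction_of(Named("A:1"), Named("A:1")) == Named("A:1")


class TestParse:
    def test_single_term_with_parent(self):
        text = HEADER + (
            "[Term]\nid: GO:0008152\nname: metabolic process\n\n"
            "[Term]\nid: GO:0009056\nname: catabolic process\n"
            "is_a: GO:0008152\n"
        )
        ont = parse_obo(text)
        assert set(ont.terms) == {"GO:0008152", "GO:0009056"}
        assert ont.terms["GO:0009056"].told_parents == {"GO:0008152"}

    def test_empty_document(self):
        ont = parse_obo("format-version: 1.4\n")
        assert len(ont.terms) == 0 and len(ont.properties) == 0

    # Expected conjunctions below were derived by hand-mapping each
    # intersection_of stanza to its genus-differentia conjunction.
    @pytest.mark.parametrize(
        "stanza_lines,expected",
        [
            (
                ["intersection_of: GO:0009056",
                 "intersection_of: has_input CHEBI:27656"],
                Conjunction((Named("GO:0009056"),
                             Existential("has_input", Named("CHEBI:27656")))),
            ),
            (
                ["intersection_of: GO:0008152",
                 "intersection_of: has_input CHEBI:27656",
                 "intersection_of: has_output GO:0009056"],
                Conjunction((Named("GO:0008152"),
                             Existential("has_input", Named("CHEBI:27656")),
                             Existential("has_output", Named("GO:0009056")))),
            ),
            (
                ["intersection_of: has_input CHEBI:27656",
                 "intersection_of: GO:0009056"],
                Conjunction((Named("GO:0009056"),
                             Existential("has_input", Named("CHEBI:27656")))),
            ),
            (
                ["intersection_of: GO:0009056",
                 "intersection_of: has_output CHEBI:27656",
                 "intersection_of: has_input CHEBI:27656"],
                Conjunction((Named("GO:0009056"),
                             Existential("has_output", Named("CHEBI:27656")),
                             Existential("has_input", Named("CHEBI:27656")))),
            ),
            (
                ["intersection_of: GO:0008152",
                 "intersection_of: part_of GO:0009056"],
                Conjunction((Named("GO:0008152"),
                             Existential("part_of", Named("GO:0009056")))),
            ),
        ],
    )
    def test_intersection_of_builds_conjunction(self, stanza_lines, expected):
        text = HEADER + (
            "[Term]\nid: GO:0008152\nname: m\n\n"
            "[Term]\nid: GO:0009056\nname: c\nis_a: GO:0008152\n\n"
            "[Term]\nid: CHEBI:27656\nname: camptothecin\n\n"
            "[Term]\nid: GO:0000001\nname: defined\n"
            + "\n".join(stanza_lines)
            + "\n\n[Typedef]\nid: has_input\n\n[Typedef]\nid: has_output\n"
            "\n[Typedef]\nid: part_of\n"
        )
        ont = parse_obo(text)
        assert ont.terms["GO:0000001"].logical_def == expected

    def test_malformed_intersection_of_rejected(self):
        text = HEADER + (
            "[Term]\nid: GO:0000001\nname: a\n"
            "intersection_of: GO:0000001\n"
        )
        with pytest.raises(OboParseError):
            parse_obo(text)

    def test_duplicate_id_rejected(self):
        text = HEADER + "[Term]\nid: GO:1\nname: a\n\n[Term]\nid: GO:1\nname: b\n"
        with pytest.raises(OboParseError, match="duplicate term id"):
            parse_obo(text)

    def test_duplicate_label_rejected(self):
        text = HEADER + "[Term]\nid: GO:1\nname: a\n\n[Term]\nid: GO:2\nname: a\n"
        with pytest.raises(OboParseError, match="duplicate label"):
            parse_obo(text)

    def test_dangling_reference_errors_unless_external(self):
        text = HEADER + "[Term]\nid: GO:1\nname: a\nis_a: CHEBI:9\n"
        with pytest.raises(OboParseError, match="dangling"):
            parse_obo(text)
        ont = parse_obo(text, external_prefixes={"CHEBI"})
        assert ont.terms["CHEBI:9"].stub

    def test_synonym_and_def_lines(self):
        text = HEADER + (
            "[Term]\nid: GO:1\nname: a\n"
            'def: "Some definition." [PMID:1, PMID:2]\n'
            'synonym: "alias" EXACT []\n'
        )
        term = parse_obo(text).terms["GO:1"]
        assert term.definition == "Some definition."
        assert term.def_xrefs == ("PMID:1", "PMID:2")
        assert term.synonyms == (("alias", "EXACT"),)

    def test_unknown_tags_preserved_verbatim(self):
        text = HEADER + "[Term]\nid: GO:1\nname: a\nxref: Wikipedia:thing\n"
        ont = parse_obo(text)
        assert ont.terms["GO:1"].extra_lines == ("xref: Wikipedia:thing",)
        assert "xref: Wikipedia:thing" in write_obo(ont)

    def test_agrees_with_obonet_on_structure(self, mini_ont):
        """Independent cross-check: obonet reads the same ids and is_a edges."""
        obonet = pytest.importorskip("obonet")
        graph = obonet.read_obo(io.StringIO(write_obo(mini_ont)))
        assert set(graph.nodes) >= set(mini_ont.terms)
        for term in mini_ont.terms.values():
            got = set(graph.nodes[term.id].get("is_a", []))
            assert got == term.told_parents


class TestWrite:
    def test_roundtrip_fixtures(self, fig_ont, mini_ont):
        for ont in (fig_ont, mini_ont):
            assert parse_obo(write_obo(ont)) == ont

    def test_roundtrip_random_ontologies(self):
        for seed in range(10):
            ont = random_ontology(RandomOntologySpec(n_classes=15, seed=seed))
            assert parse_obo(write_obo(ont)) == ont

    def test_serialization_is_deterministic(self, mini_ont):
        assert write_obo(mini_ont) == write_obo(parse_obo(write_obo(mini_ont)))

    def test_obsolete_stanza_shape(self):
        ont = parse_obo(HEADER + "[Term]\nid: GO:1\nname: gone\nis_obsolete: true\n")
        text = write_obo(ont)
        stanza = text.split("[Term]")[1]
        assert "is_obsolete: true" in stanza
        assert "is_a:" not in stanza and "relationship:" not in stanza


class TestEditing:
    def test_apply_new_term_adds_and_rewrites(self, fig_ont):
        before = write_obo(fig_ont)
        term = TermRecord(id="GO:2000001", label="new leaf",
                          told_parents={"GO:0009056"})
        out = apply_new_term(fig_ont, term)
        assert len(out.terms) == len(fig_ont.terms) + 1
        assert write_obo(fig_ont) == before  # input untouched

        rewritten = apply_new_term(
            fig_ont,
            TermRecord(id="GO:2000002", label="mid",
                       told_parents={"GO:0008152"}),
            [("GO:0009056", "GO:0008152", "GO:2000002")],
        )
        parents = rewritten.terms["GO:0009056"].told_parents
        assert "GO:2000002" in parents and "GO:0008152" not in parents

    def test_apply_new_term_only_touches_new_term_and_rewrite_children(self, mini_ont):
        term = TermRecord(id="GO:2000003", label="leafy",
                          told_parents={"GO:0008150"})
        out = apply_new_term(mini_ont, term)
        for cid, rec in mini_ont.terms.items():
            assert out.terms[cid] == rec

    def test_apply_new_term_id_collision(self, fig_ont):
        with pytest.raises(DuplicateIdError):
            apply_new_term(fig_ont, TermRecord(id="GO:0009056", label="x"))

    def test_obsolete_term_clears_links_and_keeps_label(self, fig_ont):
        out = obsolete_term(fig_ont, "GO:0009822", "redundant")
        rec = out.terms["GO:0009822"]
        assert rec.obsolete and rec.label == "alkaloid catabolic process"
        assert not rec.told_parents and rec.logical_def is None
        assert rec.comment == "redundant"
        assert len(out.terms) == len(fig_ont.terms)

    def test_obsolete_parent_warns_on_next_parse(self, fig_ont):
        out = obsolete_term(fig_ont, "GO:0008152", "merged elsewhere")
        with pytest.warns(OboLoadWarning):
            reparsed = parse_obo(write_obo(out))
        # children keep their told is_a lines to the obsolete parent
        assert "GO:0008152" in reparsed.terms["GO:0009056"].told_parents

    def test_obsolete_unknown_or_twice(self, fig_ont):
        with pytest.raises(UnknownClassError):
            obsolete_term(fig_ont, "GO:9999999", "nope")
        once = obsolete_term(fig_ont, "GO:0009822", "r")
        with pytest.raises(TermforgeError):
            obsolete_term(once, "GO:0009822", "r")
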