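"""Completion-rule reasoner: normalization, saturation, classification,
hypothetical placement, and agreement with the structural oracle."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from termforge.errors import IncoherentOntologyError, UnknownClassError
from termforge.expressions import Conjunction, Existential, Named
from termforge.fixtures import (
    ALKALOID_CATABOLIC_PROCESS,
    CAMPTOTHECIN,
    CATABOLIC_PROCESS,
    METABOLIC_PROCESS,
    RandomOntologySpec,
    camptothecin_fixture,
    random_candidate,
    random_ontology,
)
from termforge.obo import Ontology, PropertyRecord, TermRecord, write_obo
from termforge.reasoner import (
    BOTTOM,
    TOP,
    classify,
    normalize,
    place,
    relation_rewrites_for,
    saturate,
    subclass_closure,
)
from termforge.structural import StructuralReasoner


def _ont(terms, props=(), disjoints=()):
    """Small helper for hand-built in-memory ontologies."""
    ont = Ontology()
    for pid, parents, transitive in props:
        ont.properties[pid] = PropertyRecord(id=pid, parents=set(parents),
                                             transitive=transitive)
    for cid, parents, logical_def in terms:
        ont.terms[cid] = TermRecord(id=cid, label=cid.lower(),
                                    told_parents=set(parents),
                                    logical_def=logical_def)
    ont.disjoint_pairs = {frozenset(p) for p in disjoints}
    return ont


class TestNormalize:
    def test_equivalence_axiom_yields_both_directions(self):
        ont = _ont(
            [("T:A", [], Conjunction((Named("T:G"),
                                      Existential("r", Named("T:B"))))),
             ("T:G", [], None), ("T:B", [], None)],
            props=[("r", [], False)],
        )
        ax = normalize(ont)
        assert ("T:A", "T:G") in ax.atomic_subs
        assert ("T:A", "r", "T:B") in ax.exist_rhs
        # ∃r.B ⊑ F1 and G ⊓ F1 ⊑ A with a fresh F1
        (fresh,) = ax.fresh_names
        assert ("r", "T:B", fresh) in ax.exist_lhs
        assert ("T:G", fresh, "T:A") in ax.conj_subs

    def test_is_a_only_ontology_normalizes_to_edge_set(self):
        ont = _ont([("T:A", ["T:B"], None), ("T:B", [], None)])
        ax = normalize(ont)
        assert ax.atomic_subs == {("T:A", "T:B")}
        assert not ax.conj_subs and not ax.exist_rhs and not ax.exist_lhs
        assert not ax.fresh_names

    def test_disjoint_pair_encoded_as_bottom(self):
        ont = _ont([("T:A", [], None), ("T:B", [], None)],
                   disjoints=[("T:A", "T:B")])
        assert normalize(ont).bottom_subs == {("T:A", "T:B")}

    def test_fresh_names_are_stable_across_runs(self):
        ont = camptothecin_fixture()
        assert normalize(ont).fresh_names == normalize(ont).fresh_names


class TestSaturate:
    def test_worked_example_superclasses(self):
        ont = camptothecin_fixture()
        expr = Conjunction((Named(CATABOLIC_PROCESS),
                            Existential("has_input", Named(CAMPTOTHECIN))))
        closure = saturate(normalize(ont, extra_defs=[("TG:X", expr)]))
        assert {ALKALOID_CATABOLIC_PROCESS, CATABOLIC_PROCESS,
                METABOLIC_PROCESS} <= closure.S["TG:X"]

    def test_empty_axioms_initialize_reflexively(self):
        ont = _ont([("T:A", [], None)])
        closure = saturate(normalize(ont))
        assert closure.S["T:A"] == {"T:A", TOP}

    def test_atomic_chain(self):
        ont = _ont([("T:A", ["T:B"], None), ("T:B", ["T:C"], None),
                    ("T:C", [], None)])
        closure = saturate(normalize(ont))
        assert "T:C" in closure.S["T:A"]

    def test_disjoint_conjunction_is_unsatisfiable(self):
        ont = _ont(
            [("T:A", [], None), ("T:B", [], None),
             ("T:C", [], Conjunction((Named("T:A"), Named("T:B"))))],
            disjoints=[("T:A", "T:B")],
        )
        closure = saturate(normalize(ont))
        assert "T:C" in closure.unsatisfiable
        assert BOTTOM in closure.S["T:C"]

    def test_role_hierarchy_and_transitivity(self):
        # part_of transitive; A part_of B part_of C entails A part_of C,
        # and the defined class ∃part_of.C recognizes A
        ont = _ont(
            [("T:A", [], None), ("T:B", [], None), ("T:C", [], None),
             ("T:D", [], Conjunction((Named("T:R"),
                                      Existential("part_of", Named("T:C"))))),
             ("T:R", [], None)],
            props=[("part_of", [], True)],
        )
        ont.terms["T:A"].relationships = {("part_of", "T:B")}
        ont.terms["T:B"].relationships = {("part_of", "T:C")}
        ont.terms["T:A"].told_parents = {"T:R"}
        closure = saturate(normalize(ont))
        assert ("T:A", "T:C") in closure.R["part_of"]
        assert "T:D" in closure.S["T:A"]


class TestClassify:
    def test_direct_supers_in_mini_ontology(self, mini_ont):
        tax = classify(mini_ont)
        assert tax.direct_supers[CATABOLIC_PROCESS] == {METABOLIC_PROCESS}
        assert tax.direct_supers["GO:0008150"] == frozenset()

    def test_identical_definitions_merge_into_equiv_group(self):
        d = Conjunction((Named("T:G"), Existential("r", Named("T:F"))))
        ont = _ont([("T:A", [], d), ("T:B", [], d),
                    ("T:G", [], None), ("T:F", [], None)],
                   props=[("r", [], False)])
        tax = classify(ont)
        assert {"T:A", "T:B"} in [set(g) for g in tax.equiv_groups]
        # brute-force: both directions entailed
        closure = saturate(normalize(ont))
        assert "T:B" in closure.S["T:A"] and "T:A" in closure.S["T:B"]

    def test_incoherent_ontology_is_an_error(self):
        ont = _ont(
            [("T:A", [], None), ("T:B", [], None),
             ("T:C", ["T:A", "T:B"], None)],
            disjoints=[("T:A", "T:B")],
        )
        with pytest.raises(IncoherentOntologyError) as err:
            classify(ont)
        assert "T:C" in err.value.unsatisfiable

    def test_taxonomy_is_a_transitive_reduction(self):
        for seed in range(20):
            ont = random_ontology(RandomOntologySpec(n_classes=20, seed=seed))
            tax = classify(ont)
            closure = saturate(normalize(ont))
            for child, parents in tax.direct_supers.items():
                for p in parents:
                    # no other direct parent lies strictly between
                    for q in parents:
                        if q != p and p in closure.S[q] and q not in closure.S[p]:
                            pytest.fail(f"edge {child}->{p} implied via {q}")


class TestOracleAgreement:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_closure_matches_structural_oracle(self, seed):
        spec = RandomOntologySpec(
            n_classes=5 + seed % 26, n_properties=1 + seed % 3,
            p_isa=0.08, p_def=0.35, seed=seed,
        )
        ont = random_ontology(spec)
        closure = saturate(normalize(ont))
        named = {t.id for t in ont.active_terms()}
        assert closure.named_subsumptions(include=named) == (
            StructuralReasoner(ont).named_subsumptions()
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotonicity_adding_an_axiom_never_retracts(self, seed):
        ont = random_ontology(RandomOntologySpec(n_classes=15, seed=seed))
        before = saturate(normalize(ont)).named_subsumptions()
        rng = random.Random(seed)
        ids = sorted(ont.terms)
        child, parent = rng.sample(ids, 2)
        ont.terms[child].told_parents.add(parent)
        after = saturate(normalize(ont)).named_subsumptions()
        assert before <= after


class TestPlace:
    def test_worked_example_placement(self, fig_ont):
        expr = Conjunction((Named(CATABOLIC_PROCESS),
                            Existential("has_input", Named(CAMPTOTHECIN))))
        result = place(fig_ont, expr)
        assert result.direct_supers == {ALKALOID_CATABOLIC_PROCESS}
        assert result.equivalents == frozenset()
        assert result.satisfiable and result.ontology_coherent

    def test_existing_named_class_is_its_own_equivalent(self, fig_ont):
        result = place(fig_ont, Named(CATABOLIC_PROCESS))
        assert result.equivalents == {CATABOLIC_PROCESS}
        assert result.direct_supers == {METABOLIC_PROCESS}

    def test_disjoint_conjunction_unsatisfiable(self):
        ont = _ont([("T:A", [], None), ("T:B", [], None)],
                   disjoints=[("T:A", "T:B")])
        result = place(ont, Conjunction((Named("T:A"), Named("T:B"))))
        assert not result.satisfiable

    def test_place_does_not_mutate_ontology(self, mini_ont):
        before = write_obo(mini_ont)
        place(mini_ont, Conjunction((Named(CATABOLIC_PROCESS),
                                     Existential("has_input",
                                                 Named(CAMPTOTHECIN)))))
        assert write_obo(mini_ont) == before

    def test_unknown_reference_rejected(self, fig_ont):
        with pytest.raises(UnknownClassError):
            place(fig_ont, Named("GO:0000000"))


class TestRewrites:
    def test_intermediate_insertion_rewrites_child(self, mini_ont):
        # generalize alkaloid catabolic process: its told parent
        # (catabolic process) is a superclass of the new class, so the
        # child is re-attached to the new class
        expr = Conjunction((Named(CATABOLIC_PROCESS),
                            Existential("has_participant", Named("CHEBI:22315"))))
        pl = place(mini_ont, expr)
        assert ALKALOID_CATABOLIC_PROCESS in pl.direct_subs
        rewrites = relation_rewrites_for(mini_ont, pl, "GO:2000099")
        assert (ALKALOID_CATABOLIC_PROCESS, CATABOLIC_PROCESS,
                "GO:2000099") in rewrites

    def test_leaf_insertion_needs_no_rewrites(self, mini_ont):
        expr = Conjunction((Named(CATABOLIC_PROCESS),
                            Existential("has_input", Named("TEST:0000301"))))
        pl = place(mini_ont, expr)
        assert pl.direct_subs == frozenset()
        assert relation_rewrites_for(mini_ont, pl, "GO:2000099") == []

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_incremental_equals_batch(self, seed):
        """place + apply(+rewrites) + classify == classify of the
        pre-asserted ontology."""
        from termforge.obo import apply_new_term

        rng = random.Random(seed)
        ont = random_ontology(RandomOntologySpec(
            n_classes=18, n_properties=2, p_isa=0.1, p_def=0.4, seed=seed))
        expr = random_candidate(ont, rng,
                                prefer_intermediate=bool(seed % 2))
        if expr is None:
            return
        pl = place(ont, expr)
        if pl.equivalents or not pl.satisfiable:
            return
        new_id = "TEST:9999999"
        term = TermRecord(id=new_id, label="candidate term",
                          told_parents=set(pl.direct_supers),
                          logical_def=expr)
        incremental = apply_new_term(
            ont, term, relation_rewrites_for(ont, pl, new_id))
        batch = apply_new_term(ont, term)
        tax_i, tax_b = classify(incremental), classify(batch)
        assert tax_i.direct_supers == tax_b.direct_supers
        assert tax_i.direct_subs == tax_b.direct_subs


class TestSubclassClosure:
    def test_branch_closures_are_disjoint(self, mini):
        ont, subsets = mini
        mf = subclass_closure(ont, subsets["MF"])
        bp = subclass_closure(ont, subsets["BP"])
        assert mf and bp and not (mf & bp)

    def test_leaf_root_is_reflexive(self, mini_ont):
        assert subclass_closure(mini_ont, [CAMPTOTHECIN]) == {CAMPTOTHECIN}

    def test_union_over_multiple_roots(self, mini):
        ont, subsets = mini
        both = subclass_closure(ont, subsets["plant"] + subsets["cell"])
        assert both == (subclass_closure(ont, subsets["plant"])
                        | subclass_closure(ont, subsets["cell"]))

    def test_defined_classes_are_found_under_logical_ancestors(self, mini_ont):
        # alkaloid catabolic process sits under metabolic process via its
        # definition, not only via told links
        closure = subclass_closure(mini_ont, [METABOLIC_PROCESS])
        assert ALKALOID_CATABOLIC_PROCESS in closure

    def test_unknown_root_rejected(self, mini_ont):
        with pytest.raises(UnknownClassError):
            subclass_closure(mini_ont, ["GO:0000000"])
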