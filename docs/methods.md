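# Methods

This note documents the models and procedures implemented in
`termforge`, the parameters that matter, and the design decisions
taken where the design was genuinely open.

## Supported logic and the OBO dialect

The logical language is the EL fragment sufficient for
genus-differentia ("cross-product") class definitions as used by GO
and allied OBO ontologies: named classes, existential restrictions
`∃r.C`, and conjunctions, plus a role hierarchy (`r ⊑ s`), role
transitivity, and pairwise class disjointness interpreted as
`A ⊓ B ⊑ ⊥`.  No inverse roles, cardinality restrictions, nominals or
property chains beyond self-transitivity.  Every pattern in the
shipped template catalogue lives in this fragment, which is also what
keeps subsumption polynomial.

The OBO reader/writer handles a fixed tag subset (header
`format-version`/`ontology`; Term `id, name, namespace, def, comment,
synonym, is_a, relationship, intersection_of, is_obsolete,
created_by, creation_date`; Typedef `id, name, is_a, is_transitive`).
A stanza with exactly one bare `intersection_of:` line (the genus) and
one or more two-argument lines (the differentiae) is interpreted as an
equivalence axiom.  Unknown tag lines are preserved verbatim per
stanza and re-emitted, so richer documents round-trip losslessly at
the text level without being interpreted.  Serialization is canonical
(stanzas sorted by id, fixed tag order, set-valued tags sorted):
writing the same ontology value twice is byte-identical, and
`parse(write(o))` is structurally equal to `o`.  Degenerate inputs are
load-time errors (duplicate ids, duplicate labels among non-obsolete
terms, malformed intersection blocks, dangling references), except
that references with a configured *external prefix* (e.g. CHEBI while
loading a GO fragment) auto-create flagged stub terms, mirroring
multi-ontology loading without implementing imports.  Since the tag
subset has no disjointness tag, disjoint pairs exist only on
programmatically built ontologies; this keeps the round-trip guarantee
exact.

Obsoletion keeps the original label (searchability) and records the
reason in `comment:`; told parents, relationships and the logical
definition are cleared.  Children pointing at an obsolete parent keep
their `is_a` lines and trigger a load-time warning on the next parse.

## Classification: normalization + completion rules

`normalize` translates the ontology into EL normal form over named
classes and fresh names: told `is_a` → `A ⊑ B`; relationship lines →
`A ⊑ ∃r.B`; an equivalence `A ≡ G ⊓ ∃r.B ⊓ …` into `A ⊑ G`,
`A ⊑ ∃r.B`, `∃r.B ⊑ F` (fresh `F`), and a binary conjunction chain
`G ⊓ F ⊑ A`.  Fresh names are deterministic functions of the source
axiom's canonical serialization, so repeated normalization is
reproducible and identical sub-expressions share names.

`saturate` computes the least fixpoint of the standard completion
rules over superclass sets `S(·)` and role links `R(·)`:

| rule | premise | conclusion |
|------|---------|------------|
| CR1 | `A' ∈ S(A)`, `A' ⊑ B` | `B ∈ S(A)` |
| CR2 | `A1, A2 ∈ S(A)`, `A1 ⊓ A2 ⊑ B` | `B ∈ S(A)` |
| CR3 | `A' ∈ S(A)`, `A' ⊑ ∃r.B` | `(A,B) ∈ R(r)` |
| CR4 | `(A,B) ∈ R(r)`, `B' ∈ S(B)`, `∃r.B' ⊑ C` | `C ∈ S(A)` |
| CR5 | `(A,B) ∈ R(r)`, `r ⊑ s` | `(A,B) ∈ R(s)` |
| CR6 | `trans(r)`, `(A,B),(B,C) ∈ R(r)` | `(A,C) ∈ R(r)` |
| CR⊥ | `⊥ ∈ S(B)`, `(A,B) ∈ R(r)` | `⊥ ∈ S(A)` |

implemented as an indexed worklist; termination follows from the
finite vocabulary.  `classify` then builds the taxonomy: equivalence
groups (mutual entailment), and the transitive reduction of the strict
order between groups as the direct super/sub maps.  Obsolete classes
are excluded; an unsatisfiable named class makes `classify` fail with
the unsatisfiable set (an incoherent ontology should be repaired, not
silently classified).

### Hypothetical placement

`place(ontology, expr)` asserts `TEMP ≡ expr` into a freshly
normalized axiom set, saturates from scratch, and reads off
equivalents, direct superclasses, direct subclasses and
satisfiability; the input ontology value is never touched, so revert
is the identity.  Saturation from scratch (rather than incremental
closure maintenance) is a deliberate correctness-over-speed choice:
the workloads are desk-scale (10²–10³ classes), where a full
saturation takes milliseconds.  `ontology_coherent` reports the
sanity check performed before the candidate queries are trusted.  For
an unsatisfiable candidate the result sets are returned empty rather
than as the degenerate "everything" answer.

### is_a rewrites for intermediate insertions

When a new class lands *between* existing classes, the told graph
must follow: for each inferred direct subclass `S` of the new class,
every told parent `P` of `S` that is an entailed superclass of the
new class is replaced by the new class (`S→P` becomes `S→new`).
After committing the term plus these rewrites, the transitive
reduction of the told `is_a` graph coincides with the batch-classified
taxonomy — the "incremental = batch" property that the test suite and
acceptance script verify on randomized cases.

### The structural oracle

`structural.py` contains an intentionally different subsumption
algorithm used only for cross-validation: a sequent-style closure of
the `⊑` relation over the set of expressions occurring in the
ontology (reflexivity/transitivity, told edges, both directions of
each definition, conjunction introduction/elimination, existential
monotonicity through the role hierarchy, transitive-role
composition), iterated in passes to a fixpoint.  On acyclic
ontologies in the supported fragment it must agree with the
completion-rule reasoner on every named-class subsumption; the suite
checks this on hundreds of seeded random ontologies.  The oracle does
not interpret disjointness — the random test ontologies carry none —
so coherence-related behaviour is tested separately on hand-built
cases with hand-computed expectations.

## Templates

Templates are data, not code.  A template declares typed input fields
(class fields restricted to named subsets, 1–3 class fields per
template), a logical pattern, label/definition text patterns, and
synonym rules.  The pattern grammar is one line per template:

```
pattern   := conjunct (" and " conjunct)*
conjunct  := genus | relation | "[" relation "]"        # [...] optional
genus     := CURIE | 'label' | ?VAR
relation  := 'relation label' some (CURIE | ?VAR | 'label')
```

Relation labels resolve through a label→property map in the same
file; quoted class labels resolve against the loaded ontology at
instantiation time.  A bracketed conjunct is optional and tied to the
(optional) field of its single variable; leaving that field unbound
drops the conjunct and every `[[ ... ]]`-delimited segment of the
text patterns that mentions it.  Text placeholders are `[X]` (bound
class label) and `[X.id]` (CURIE).  Synonym rules apply their pattern
to each synonym of the bound class; the generated scope is the rule's
scope when the source synonym is EXACT and RELATED otherwise (a
non-exact source cannot justify an exact generated synonym).

Binding validation returns failures as data: missing required fields,
class values outside the reasoner-computed subset closure of the
field's roots, and a missing or malformed (`PREFIX:value`) literature
reference.  Instantiation is deterministic and total on validated
bindings.

The shipped catalogue (`data/go_templates.yaml`, 55 entries)
transcribes the standard GO cross-product patterns — regulation
(BP/MF, three polarities), involved-in/occurs-in composition,
chemical transport/binding/metabolism/homeostasis/response families,
component transport and assembly, plant and metazoan development,
cell-type patterns, protein localization, organismal granularity, and
two-chemical metabolic variants.  The label/definition text patterns
in the catalogue are this package's house conventions for those
patterns (flagged as such in the file); the logical patterns and
subset restrictions are the normative content.

## Suggestion index

Autocompletion entries are the labels and synonyms of all
non-obsolete classes, each tagged with every configured subset whose
subclass closure contains the class (a subset may have roots in
several source ontologies).  Query ranking is a strict four-tier
order — whole-label prefix, label word prefix, synonym prefix,
substring — with ties broken by shorter label then class id, making
the ranking a deterministic total order.  The tier scheme itself is a
design choice of this package: prefix-first matches user expectation
and is trivially testable.  The index is rebuilt in memory on load;
at desk scale persistence would add state without measurable benefit.

## Request pipeline

* **Identifiers.**  `IdPolicy(prefix, width, range)` allocates the
  smallest free integer in the configured range, zero-padded; ids
  already present in the loaded ontology count as allocated.  The
  allocation set is persisted (atomic write) *before* the id is
  returned, so a crash cannot reissue an id.
* **Queue.**  An append-only JSON-lines event log (`submit`,
  `review`, `committed` events).  Replaying the log reconstructs the
  queue exactly; this is the crash-tolerance and restart story, and
  replaces an embedded database with the simplest equivalent.
  Request ids are strictly increasing.
* **Submission** runs validate → instantiate → place and refuses
  duplicates (the error names the equivalent existing class),
  unsatisfiable candidates, and incoherent ontologies; provenance
  (`created_by`, `creation_date`) is stamped from the requester and a
  injectable clock (deterministic in tests).  Authorization is a
  config allow-list of requester identifiers; template and free-form
  submission use separate lists.
* **Review** offers approve / modify / obsolete — no reject, because
  the identifier is already permanent.  Edits may touch only label,
  definition and synonyms; the logical definition is immutable at
  review.  An obsoleted request is later committed as an obsolete
  stub term so its identifier stays resolvable (the project-standard
  resolution of the no-delete rule; an obsoleted *request* leaves the
  same artifact as an obsoleted class).
* **Commit** processes each selected request separately, in
  request-id order, against a freshly reloaded ontology file: quick
  checks re-run (id unused, no equivalent named class, still
  satisfiable, label still unique), told parents are asserted as the
  freshly inferred direct superclasses, is_a rewrites applied, and
  the file replaced atomically; one changelog line per request.  A
  failure (e.g. a stale duplicate created by an earlier commit in the
  same batch) aborts only that request.

## Free-form requests

Experienced curators can request classes outside any template (told
parents + relationships, no equivalence axiom).  Since the reasoner
cannot catch duplicates without a logical definition, the label is
screened against all existing labels and synonyms, case-folded:

* warn when edit distance ≤ 2, **or** one string contains the other
  with length difference ≤ 3;
* an exact match (distance 0) always blocks;
* near matches block unless explicitly dismissed (`force`).

The metric is a package design choice — the smallest rule family that
is symmetric in the near case, has a testable threshold, and fires on
the canonical omegasome/megasome pair (distance 1 and substring)
while staying silent on clearly distinct labels such as
ribosome/megasome (distance 4, not a substring).  Edit distances are
computed with `edlib`.

## Fixtures and the random-ontology generator

`camptothecin_fixture()` is the worked inference example: catabolic ⊑
metabolic process, camptothecin ⊑ alkaloid, and *alkaloid catabolic
process* ≡ catabolic ⊓ ∃has_input.alkaloid, so the candidate
catabolic ⊓ ∃has_input.camptothecin must be placed under it.
`mini_go_chebi()` (~55 classes, 27 relations) spans the BP/MF/CC
branches plus ChEBI, PO, CL, Uberon and PATO roots, every relation and
subset root used by the shipped catalogue, realistic property
hierarchy (`has_input ⊑ has_participant`, `imports/exports ⊑
transports-or-maintains-localization-of`, transitive `part_of`), and
the `megasome` class for the similarity example.  Fixture ids reuse
well-known CURIEs where a conventional id exists (e.g. GO:0009822,
CHEBI:27656); invented classes use a `TEST:` prefix.

`random_ontology(spec)` draws acyclic ontologies deterministically
from a seed: told `is_a` edges are independent Bernoulli(`p_isa`)
draws over ordered class pairs (later-below-earlier, hence acyclic);
a fraction `p_def` of classes (from the third onward) receives a
genus-differentia definition referencing strictly earlier classes,
with a second differentia with probability 0.3; optional relationship
lines, transitive properties and a random role hierarchy are
controlled by defaulted extras (`p_rel=0.08`, `p_transitive=0.25`,
`p_role_sub=0.25`).  Defaults `p_isa=0.08`, `p_def=0.3` give sparse
DAGs with enough defined classes for non-trivial inference at 10–30
classes; the empirical edge and definition rates are
distribution-tested against the spec over 1,000 seeded draws.

**What the generator does and does not emulate.**  It reproduces the
structural features that drive the reasoning machinery (DAG-shaped
told hierarchies, cross-referencing genus-differentia definitions,
role hierarchies/transitivity) but not the statistical texture of real
ontologies: no realistic label vocabulary, no synonym distributions,
no disjointness axioms, no deep balanced branches, and class counts
three orders of magnitude below a full GO.  Passing the randomized
suites therefore demonstrates logical correctness of
classification/placement at desk scale, not performance or curation
quality on production ontologies.

## Problem sizes used in tests and the acceptance script

Oracle agreement runs 200 seeded ontologies of 5–30 classes;
incremental-vs-batch runs 100 pipeline round-trips on 16-class
ontologies (roughly half of them intermediate insertions that force
rewrites); duplicate defense runs 50 randomized template/chemical
combinations committed sequentially to one growing workspace;
identifier safety issues 1,000 ids with queue/policy restarts every
100.  These sizes were chosen as the smallest that exercise every
code path with comfortable statistical coverage while keeping the
whole suite in the low seconds.

## Known limitations

* No OWL serialization (RDF/XML, functional syntax); OBO only.
* Logical definitions are limited to one genus plus existential
  differentiae with named fillers when read from OBO (arbitrary
  nesting is supported for programmatic placement queries).
* No `union_of`, `equivalent_to`-between-named-classes,
  `disjoint_from` tags; annotations outside the supported tag set are
  preserved but not interpreted.
* The reasoner is sound and complete only for the stated EL fragment;
  there is no explanation/justification machinery.
* The queue is single-writer; concurrent curators would need file
  locking that is deliberately out of scope.
* Free-form similarity screening is lexical only; it cannot catch
  semantically duplicate classes with unrelated labels.
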