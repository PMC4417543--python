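# termforge

Template-driven generation of new ontology classes, with
reasoning-based validation and a reviewable request queue.

## The problem

Biomedical ontologies such as the Gene Ontology grow largely through
class requests from biocurators, and most requested classes follow a
small number of design patterns: *regulation of X*, *X catabolic
process*, *X transport from F to T*, and so on.  Handling such
requests by hand is slow and error-prone, and the resulting classes
often lack the OWL equivalence axioms that make automatic
classification possible.  `termforge` makes the patterns executable:
an ontology engineer encodes each pattern once as a declarative
template, after which a curator can fill in the template's input
fields and obtain a complete candidate class — label, textual
definition, synonyms, and a genus-differentia logical definition —
that a reasoner then validates and places in the hierarchy before the
request ever reaches a reviewer.

## The core machinery

Every template carries an equivalence-axiom skeleton in the EL
fragment of OWL (conjunction + existential restriction), e.g. for the
chemical-catabolism pattern

```
?C ≡ 'catabolic process' ⊓ ∃ has_input . ?X        (X a ChEBI class)
```

Filling `X = camptothecin (CHEBI:27656)` grounds the axiom.  The
built-in structural reasoner normalizes all told `is_a` links,
relationship lines and equivalence axioms into EL normal form and
saturates the standard completion rules (CR1–CR6 plus a bottom rule
for disjointness), yielding for every class the full set of entailed
superclasses in polynomial time.  On top of that closure the package
answers the questions that gate a new class:

* is the candidate **equivalent to an existing named class**? (duplicate
  defense — the request is rejected with the existing id);
* is it **satisfiable**, and is the ontology still coherent?
* what are its **direct super- and subclasses**?  Because camptothecin
  is an alkaloid, `catabolic process ⊓ ∃has_input.camptothecin` is
  placed under *alkaloid catabolic process* (GO:0009822), not merely
  under *catabolic process*;
* which existing children must be **re-parented** when the new class is
  inserted between existing classes (is_a rewrites).

Accepted candidates get a permanent identifier from a configured
pattern and range, enter an append-only review queue (approve /
modify / obsolete — never delete, since the identifier is already
permanent), and are committed one-by-one to the OBO file, each commit
re-running the quick checks against a freshly reloaded ontology.

## Worked example

```python
from termforge import place, classify, Named, Existential, Conjunction
from termforge.fixtures import camptothecin_fixture

ont = camptothecin_fixture()
candidate = Conjunction((
    Named("GO:0009056"),                              # catabolic process
    Existential("has_input", Named("CHEBI:27656")),   # camptothecin
))
print(place(ont, candidate))
```

prints

```
PlacementResult(equivalents=frozenset(), direct_supers=frozenset({'GO:0009822'}),
direct_subs=frozenset(), satisfiable=True, ontology_coherent=True)
```

i.e. the candidate is new (no equivalent class), satisfiable, and its
most specific entailed superclass is `GO:0009822` *alkaloid catabolic
process* — inferred, not asserted, from `camptothecin ⊑ alkaloid`.

The same flow from the shell, end to end (with a `termforge.yaml` in
the working directory wiring the ontology, identifier range and queue
paths):

```yaml
# termforge.yaml
ontologies: [go.obo]
templates: builtin
id_policy: {prefix: GO, width: 7, range_start: 2000001,
            range_end: 2001000, state: ids.json}
queue: queue.jsonl
changelog: changelog.tsv
```

```
$ termforge fixtures --name mini_go --out go.obo
$ termforge request catabolism --bind X=CHEBI:27656 \
      --ref PMID:12345 --user curator@example.org
request 1: GO:2000001 camptothecin catabolic process
direct supers: GO:0009822
$ termforge status GO:2000001
pending
$ termforge review approve 1
request 1 approved (GO:2000001)
$ termforge commit --all
1	GO:2000001	added	ok	added with parents GO:0009822
$ termforge status GO:2000001
approved
```

The shipped catalogue (`termforge templates`) contains 55 cross-product
patterns over process/function/component, ChEBI, plant-anatomy,
cell-type, anatomy and quality roots; free-form requests
(`termforge freeform`) bypass the templates but are screened against
existing labels and synonyms (requesting `omegasome` warns that
`megasome` exists at edit distance 1; the warning is dismissible with
`--force`, an exact duplicate never is).

## Layout

```
src/termforge/
  obo.py          OBO 1.4 subset reader/writer, copy-on-write editing
  expressions.py  EL class expressions (genus-differentia definitions)
  reasoner.py     completion-rule saturation, classification, placement
  structural.py   independent structural subsumption checker (oracle)
  templates.py    declarative template engine + pattern grammar
  suggest.py      subset-restricted autocompletion index
  pipeline.py     id policy, request queue, review, per-request commit
  freeform.py     non-templated requests with similarity screening
  fixtures.py     worked-example / mini-GO fixtures, random ontologies
  config.py,cli.py  application wiring and the termforge command
  data/go_templates.yaml  the shipped template catalogue
```

See `docs/methods.md` for the reasoning calculus, the template
grammar, and the design decisions in detail.
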