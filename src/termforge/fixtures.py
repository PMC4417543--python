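"""Deterministic toy ontologies and a seeded random-ontology generator.

``camptothecin_fixture`` reproduces the classic worked inference for
genus-differentia reasoning: a candidate class *catabolic process and
has_input some camptothecin* must be placed under the pre-existing
cross-product class *alkaloid catabolic process* because camptothecin
is an alkaloid.

``mini_go_chebi`` is a small multi-ontology workspace (GO biological
process / molecular function / cellular component branches plus ChEBI,
PO, CL, Uberon and PATO roots and the full relation vocabulary used by
the shipped template catalogue), sized so that every shipped template
can be validated and instantiated against it.

``random_ontology`` draws acyclic ontologies — told is_a edges are
independent Bernoulli(p_isa) draws over ordered class pairs, a
fraction p_def of classes get a genus-differentia definition that only
references earlier classes — and is the workhorse of the oracle-based
reasoner tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .expressions import Conjunction, Existential, Expr, Named
from .obo import Ontology, PropertyRecord, TermRecord

#: CURIEs used across the worked examples
CAMPTOTHECIN = "CHEBI:27656"
ALKALOID = "CHEBI:22315"
CHEMICAL_ENTITY = "CHEBI:24431"
CATABOLIC_PROCESS = "GO:0009056"
METABOLIC_PROCESS = "GO:0008152"
ALKALOID_CATABOLIC_PROCESS = "GO:0009822"


def _term(ont, cid, label, parents=(), ns="", definition="", logical_def=None,
          synonyms=(), relationships=()):
    ont.terms[cid] = TermRecord(
        id=cid,
        label=label,
        definition=definition,
        namespace=ns,
        told_parents=set(parents),
        relationships=set(relationships),
        logical_def=logical_def,
        synonyms=tuple(synonyms),
    )


def _prop(ont, pid, label=None, parents=(), transitive=False):
    ont.properties[pid] = PropertyRecord(
        id=pid,
        label=label if label is not None else pid.replace("_", " "),
        parents=set(parents),
        transitive=transitive,
    )


def camptothecin_fixture() -> Ontology:
    """The camptothecin-catabolism worked example.

    Contains metabolic/catabolic process, the ChEBI alkaloid branch
    with camptothecin, and alkaloid catabolic process defined as
    ``catabolic process and has_input some alkaloid``.
    """
    ont = Ontology(format_tag="termforge/camptothecin-test")
    _prop(ont, "has_input")
    bp = "biological_process"
    _term(ont, METABOLIC_PROCESS, "metabolic process", ns=bp)
    _term(ont, CATABOLIC_PROCESS, "catabolic process", [METABOLIC_PROCESS], ns=bp)
    _term(ont, CHEMICAL_ENTITY, "chemical entity")
    _term(ont, ALKALOID, "alkaloid", [CHEMICAL_ENTITY])
    _term(ont, CAMPTOTHECIN, "camptothecin", [ALKALOID])
    _term(
        ont,
        ALKALOID_CATABOLIC_PROCESS,
        "alkaloid catabolic process",
        [CATABOLIC_PROCESS],
        ns=bp,
        logical_def=Conjunction(
            (Named(CATABOLIC_PROCESS), Existential("has_input", Named(ALKALOID)))
        ),
    )
    return ont


def mini_go_chebi() -> tuple[Ontology, dict]:
    """A ~55-class GO/ChEBI/PO/CL/Uberon/PATO workspace plus the subset
    map (name -> root class ids) used by the shipped template catalogue."""
    ont = Ontology(format_tag="termforge/mini-go-test")

    # relation vocabulary of the template catalogue
    _prop(ont, "has_participant")
    _prop(ont, "has_input", parents=["has_participant"])
    _prop(ont, "has_output", parents=["has_participant"])
    _prop(ont, "has_intermediate", parents=["has_participant"])
    _prop(ont, "regulates")
    _prop(ont, "negatively_regulates", parents=["regulates"])
    _prop(ont, "positively_regulates", parents=["regulates"])
    _prop(ont, "regulates_level_of")
    _prop(ont, "part_of", transitive=True)
    _prop(ont, "occurs_in")
    _prop(ont, "results_in")
    _prop(ont, "transports_or_maintains_localization_of")
    _prop(ont, "imports", parents=["transports_or_maintains_localization_of"])
    _prop(ont, "exports", parents=["transports_or_maintains_localization_of"])
    _prop(ont, "has_target_start_location")
    _prop(ont, "has_target_end_location")
    _prop(ont, "results_in_assembly_of")
    _prop(ont, "results_in_disassembly_of")
    _prop(ont, "results_in_development_of")
    _prop(ont, "results_in_formation_of")
    _prop(ont, "results_in_developmental_progression_of")
    _prop(ont, "results_in_morphogenesis_of")
    _prop(ont, "results_in_structural_organization_of")
    _prop(ont, "results_in_acquisition_of_features_of")
    _prop(ont, "alters_location_of")
    _prop(ont, "capable_of")
    _prop(ont, "bearer_of")

    bp, mf, cc = "biological_process", "molecular_function", "cellular_component"

    # biological process branch
    _term(ont, "GO:0008150", "biological_process", ns=bp)
    _term(ont, METABOLIC_PROCESS, "metabolic process", ["GO:0008150"], ns=bp)
    _term(ont, CATABOLIC_PROCESS, "catabolic process", [METABOLIC_PROCESS], ns=bp)
    _term(ont, "GO:0009058", "biosynthetic process", [METABOLIC_PROCESS], ns=bp)
    _term(
        ont,
        ALKALOID_CATABOLIC_PROCESS,
        "alkaloid catabolic process",
        [CATABOLIC_PROCESS],
        ns=bp,
        logical_def=Conjunction(
            (Named(CATABOLIC_PROCESS), Existential("has_input", Named(ALKALOID)))
        ),
    )
    _term(ont, "GO:0065007", "biological regulation", ["GO:0008150"], ns=bp)
    _term(ont, "GO:0050789", "regulation of biological process",
          ["GO:0065007"], ns=bp)
    _term(ont, "GO:0006810", "transport", ["GO:0008150"], ns=bp)
    _term(ont, "GO:0055085", "transmembrane transport", ["GO:0006810"], ns=bp)
    _term(ont, "GO:0016192", "vesicle-mediated transport", ["GO:0006810"], ns=bp)
    _term(ont, "GO:0050896", "response to stimulus", ["GO:0008150"], ns=bp)
    _term(ont, "GO:0070887", "cellular response to chemical stimulus",
          ["GO:0050896"], ns=bp)
    _term(ont, "GO:0048878", "chemical homeostasis", ["GO:0008150"], ns=bp)
    _term(ont, "GO:0055082", "cellular chemical homeostasis", ["GO:0048878"], ns=bp)
    _term(ont, "GO:0022607", "cellular component assembly", ["GO:0008150"], ns=bp)
    _term(ont, "GO:0022411", "cellular component disassembly", ["GO:0008150"], ns=bp)
    _term(ont, "GO:0030154", "cell differentiation", ["GO:0008150"], ns=bp)
    _term(ont, "GO:0008104", "protein localization", ["GO:0008150"], ns=bp)
    _term(ont, "GO:0045184", "establishment of protein localization",
          ["GO:0008104"], ns=bp)
    _term(ont, "TEST:0000101", "cell migration", ["GO:0008150"], ns=bp)
    _term(ont, "TEST:0000102", "anatomical structure development",
          ["GO:0008150"], ns=bp)
    _term(ont, "TEST:0000103", "developmental maturation", ["GO:0008150"], ns=bp)
    _term(ont, "TEST:0000104", "anatomical structure morphogenesis",
          ["GO:0008150"], ns=bp)
    _term(ont, "TEST:0000105",
          "anatomical structure formation involved in morphogenesis",
          ["TEST:0000104"], ns=bp)
    _term(ont, "TEST:0000106", "anatomical structure arrangement",
          ["GO:0008150"], ns=bp)
    _term(ont, "TEST:0000107", "cell-type specific apoptotic process",
          ["GO:0008150"], ns=bp)

    # molecular function branch
    _term(ont, "GO:0003674", "molecular_function", ns=mf)
    _term(ont, "GO:0005215", "transporter activity", ["GO:0003674"], ns=mf)
    _term(ont, "GO:0022857", "transmembrane transporter activity",
          ["GO:0005215"], ns=mf)
    _term(ont, "GO:0015291",
          "secondary active transmembrane transporter activity",
          ["GO:0022857"], ns=mf)
    _term(ont, "GO:0015563", "uptake transmembrane transporter activity",
          ["GO:0022857"], ns=mf)
    _term(ont, "GO:0042626", "ATPase-coupled transmembrane transporter activity",
          ["GO:0022857"], ns=mf)
    _term(ont, "GO:0005488", "binding", ["GO:0003674"], ns=mf)

    # cellular component branch
    _term(ont, "GO:0005575", "cellular_component", ns=cc)
    _term(ont, "TEST:0000201", "membrane", ["GO:0005575"], ns=cc)
    _term(ont, "TEST:0000202", "vacuole", ["GO:0005575"], ns=cc)
    _term(ont, "TEST:0000203", "nucleus", ["GO:0005575"], ns=cc)
    _term(ont, "TEST:0000204", "megasome", ["GO:0005575"], ns=cc)
    _term(ont, "GO:0043234", "protein complex", ["GO:0005575"], ns=cc)

    # ChEBI branch
    _term(ont, CHEMICAL_ENTITY, "chemical entity")
    _term(ont, ALKALOID, "alkaloid", [CHEMICAL_ENTITY],
          synonyms=[("alkaloids", "EXACT")])
    _term(ont, CAMPTOTHECIN, "camptothecin", [ALKALOID])
    _term(ont, "TEST:0000301", "glucose", [CHEMICAL_ENTITY],
          synonyms=[("dextrose", "EXACT")])
    _term(ont, "TEST:0000302", "ethanol", [CHEMICAL_ENTITY])
    _term(ont, "TEST:0000303", "citrate", [CHEMICAL_ENTITY])
    _term(ont, "TEST:0000304", "sodium ion", [CHEMICAL_ENTITY])
    _term(ont, "TEST:0000305", "calcium ion", [CHEMICAL_ENTITY])
    _term(ont, "TEST:0000306", "lactose", [CHEMICAL_ENTITY])
    _term(ont, "TEST:0000307", "urea", [CHEMICAL_ENTITY])

    # other template roots
    _term(ont, "PO:0025131", "plant anatomical entity")
    _term(ont, "TEST:0000401", "leaf", ["PO:0025131"])
    _term(ont, "CL:0000003", "native cell")
    _term(ont, "TEST:0000402", "neuron", ["CL:0000003"])
    _term(ont, "UBERON:0001062", "anatomical entity")
    _term(ont, "TEST:0000403", "heart", ["UBERON:0001062"])
    _term(ont, "PATO:0002487", "single organism")
    _term(ont, "PATO:0002486", "multi organism")

    subsets = {
        "BP": ["GO:0008150"],
        "MF": ["GO:0003674"],
        "CC": ["GO:0005575"],
        "chebi": [CHEMICAL_ENTITY],
        "plant": ["PO:0025131"],
        "cell": ["CL:0000003"],
        "uberon": ["UBERON:0001062"],
        "regulation": ["GO:0050789"],
    }
    return ont, subsets


# ---------------------------------------------------------------------------
# Random ontologies

@dataclass
class RandomOntologySpec:
    """Parameters of the random acyclic ontology generator.

    told is_a edges are independent Bernoulli(p_isa) over ordered class
    pairs (later class below earlier class); a fraction ``p_def`` of
    eligible classes receives a genus-differentia definition whose
    genus and fillers are strictly earlier classes, keeping the
    definition graph acyclic.  The defaulted extras control optional
    relationship lines and the property box.
    """

    n_classes: int
    n_properties: int = 2
    p_isa: float = 0.08
    p_def: float = 0.3
    seed: int = 0
    p_rel: float = 0.08
    p_second_diff: float = 0.3
    p_transitive: float = 0.25
    p_role_sub: float = 0.25

    def __post_init__(self):
        for p in (self.p_isa, self.p_def, self.p_rel, self.p_second_diff,
                  self.p_transitive, self.p_role_sub):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_classes < 1:
            raise ValueError("need at least one class")


def _class_id(i: int) -> str:
    return f"TEST:{i + 1:07d}"


def random_ontology(spec: RandomOntologySpec) -> Ontology:
    """Draw a deterministic acyclic ontology for the given spec."""
    rng = random.Random(spec.seed)
    ont = Ontology(format_tag=f"termforge/random-{spec.seed}")

    for p in range(spec.n_properties):
        pid = f"r{p}"
        parents = []
        if p > 0 and rng.random() < spec.p_role_sub:
            parents = [f"r{rng.randrange(p)}"]
        _prop(ont, pid, parents=parents,
              transitive=rng.random() < spec.p_transitive)

    for i in range(spec.n_classes):
        cid = _class_id(i)
        parents = {
            _class_id(j) for j in range(i) if rng.random() < spec.p_isa
        }
        relationships = set()
        if i > 0 and spec.n_properties and rng.random() < spec.p_rel:
            relationships.add(
                (f"r{rng.randrange(spec.n_properties)}",
                 _class_id(rng.randrange(i)))
            )
        logical_def = None
        if i >= 2 and spec.n_properties and rng.random() < spec.p_def:
            genus = _class_id(rng.randrange(i))
            diffs = [
                Existential(
                    f"r{rng.randrange(spec.n_properties)}",
                    Named(_class_id(rng.randrange(i))),
                )
            ]
            if rng.random() < spec.p_second_diff:
                diffs.append(
                    Existential(
                        f"r{rng.randrange(spec.n_properties)}",
                        Named(_class_id(rng.randrange(i))),
                    )
                )
            try:
                logical_def = Conjunction((Named(genus), *diffs))
            except ValueError:
                logical_def = None  # duplicate parts collapsed below 2
        _term(ont, cid, f"test class {i + 1:03d}", parents,
              relationships=relationships, logical_def=logical_def)
    return ont


def random_candidate(
    ont: Ontology, rng: random.Random, prefer_intermediate: bool = False
) -> Expr | None:
    """Draw a genus-differentia candidate expression over *ont*.

    With ``prefer_intermediate`` the candidate generalizes an existing
    defined class so that inserting it forces is_a rewrites of that
    class (the new class lands between the defined class and one of
    its told parents).
    """
    ids = sorted(t.id for t in ont.active_terms())
    props = sorted(ont.properties)
    if not ids or not props:
        return None

    if prefer_intermediate:
        defined = [
            t for t in ont.active_terms()
            if t.logical_def is not None and t.told_parents
        ]
        rng.shuffle(defined)
        for term in defined:
            parts = term.logical_def.parts
            exts = [p for p in parts if isinstance(p, Existential)
                    and isinstance(p.filler, Named)]
            if not exts:
                continue
            ext = rng.choice(exts)
            genus = rng.choice(sorted(term.told_parents))
            filler_parents = sorted(
                ont.terms[ext.filler.id].told_parents
            ) if ext.filler.id in ont.terms else []
            filler = rng.choice(filler_parents) if filler_parents else ext.filler.id
            try:
                return Conjunction(
                    (Named(genus), Existential(ext.prop, Named(filler)))
                )
            except ValueError:
                continue
        return None

    genus = rng.choice(ids)
    filler = rng.choice(ids)
    prop = rng.choice(props)
    try:
        return Conjunction((Named(genus), Existential(prop, Named(filler))))
    except ValueError:
        return None
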