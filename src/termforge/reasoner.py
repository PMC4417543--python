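"""EL-profile structural reasoner.

Classification works in two stages.  ``normalize`` translates the
ontology's told is_a links, relationship lines, genus-differentia
equivalence axioms, property hierarchy/transitivity and disjointness
pairs into a normal form in which every axiom is one of::

    A ⊑ B          (atomic_subs)
    A1 ⊓ A2 ⊑ B    (conj_subs; disjointness uses B = ⊥)
    A ⊑ ∃r.B       (exist_rhs)
    ∃r.B ⊑ A       (exist_lhs)
    r ⊑ s          (role_subs)
    trans(r)       (role_trans)

over named classes and deterministically generated fresh names.
``saturate`` then runs the standard EL completion rules to a least
fixpoint, yielding for every class A the set S(A) of all entailed
superclasses and for every role r the derived links R(r).

On top of the closure, ``classify`` builds the taxonomy (equivalence
groups plus the transitive reduction of the strict subsumption order),
``place`` answers the hypothetical-class questions asked before a new
class is accepted (equivalent named classes, direct super- and
subclasses, satisfiability), and ``relation_rewrites_for`` derives the
is_a rewrites needed when a new class is inserted between existing
ones.  ``place`` saturates an extended axiom set built from scratch,
so the input ontology value is never touched and there is nothing to
revert.

The supported logic is EL with role hierarchies and role transitivity
plus disjointness-as-bottom: no inverse roles, cardinality or
nominals.  Every genus-differentia cross-product pattern used by OBO
ontologies fits this fragment, which is also why a polynomial-time
completion procedure suffices.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field

from .errors import (
    IncoherentOntologyError,
    TermforgeError,
    UnknownClassError,
    UnknownPropertyError,
)
from .expressions import (
    Conjunction,
    Existential,
    Expr,
    Named,
    canonical,
    is_grounded,
    iter_named,
    iter_properties,
)
from .obo import Ontology

TOP = "__top__"
BOTTOM = "__bottom__"
_FRESH = "__fresh__:"

#: temporary identifier under which ``place`` asserts the hypothetical class
TEMP_ID = "TG:HYPOTHETICAL"


@dataclass
class NormalizedAxiomSet:
    atomic_subs: set = field(default_factory=set)  # (A, B)
    conj_subs: set = field(default_factory=set)  # (A1, A2, B)
    exist_rhs: set = field(default_factory=set)  # (A, r, B)
    exist_lhs: set = field(default_factory=set)  # (r, B, A)
    role_subs: set = field(default_factory=set)  # (r, s)
    role_trans: set = field(default_factory=set)
    bottom_subs: set = field(default_factory=set)  # (A1, A2) with A1 ⊓ A2 ⊑ ⊥
    fresh_names: set = field(default_factory=set)
    classes: set = field(default_factory=set)
    properties: set = field(default_factory=set)


@dataclass
class SubsumptionClosure:
    """Least fixpoint of the completion rules."""

    S: dict  # ClassId -> set of entailed superclasses (reflexive, incl. TOP)
    R: dict  # PropertyId -> set of (ClassId, ClassId) derived role links
    unsatisfiable: set
    fresh_names: frozenset

    def named_subsumptions(self, include: set | None = None) -> set:
        """Strict entailed subsumptions over named (non-fresh) classes."""
        skip = self.fresh_names | {TOP, BOTTOM}
        out = set()
        for a, supers in self.S.items():
            if a in skip or (include is not None and a not in include):
                continue
            for b in supers:
                if b != a and b not in skip and (include is None or b in include):
                    out.add((a, b))
        return out


@dataclass
class Taxonomy:
    """Equivalence groups and the direct (transitively reduced) hierarchy."""

    direct_supers: dict  # ClassId -> frozenset of ClassId
    direct_subs: dict  # ClassId -> frozenset of ClassId
    equiv_groups: tuple  # of frozenset

    def group_of(self, class_id: str) -> frozenset:
        for g in self.equiv_groups:
            if class_id in g:
                return g
        raise UnknownClassError(f"not in taxonomy: {class_id}")


@dataclass
class PlacementResult:
    """Reasoner verdict for a candidate class expression."""

    equivalents: frozenset
    direct_supers: frozenset
    direct_subs: frozenset
    satisfiable: bool
    ontology_coherent: bool


# ---------------------------------------------------------------------------
# Normalization

def _fresh(key: str) -> str:
    return _FRESH + key


class _Normalizer:
    def __init__(self, ontology: Ontology):
        self.ont = ontology
        self.ax = NormalizedAxiomSet()
        self.ax.classes = set(ontology.terms)
        self.ax.properties = set(ontology.properties)
        self._encoded: set[str] = set()

    def check_class(self, cid: str) -> None:
        if cid not in self.ax.classes and cid not in self.ax.fresh_names:
            raise UnknownClassError(f"unknown class in expression: {cid}")

    def check_property(self, pid: str) -> None:
        if pid not in self.ax.properties:
            raise UnknownPropertyError(f"unknown relation in expression: {pid}")

    def fresh(self, key: str) -> str:
        name = _fresh(key)
        self.ax.fresh_names.add(name)
        return name

    def atom_for(self, expr: Expr) -> str:
        """A class name equivalent to *expr* (fresh for complex fillers)."""
        if isinstance(expr, Named):
            self.check_class(expr.id)
            return expr.id
        name = _fresh("eq|" + canonical(expr))
        if name not in self._encoded:
            self._encoded.add(name)
            self.ax.fresh_names.add(name)
            self.encode_equiv(name, expr)
        return name

    def encode_equiv(self, cls: str, expr: Expr) -> None:
        """Encode ``cls ≡ expr`` in both directions."""
        if isinstance(expr, Named):
            self.check_class(expr.id)
            self.ax.atomic_subs.add((cls, expr.id))
            self.ax.atomic_subs.add((expr.id, cls))
        elif isinstance(expr, Existential):
            self.check_property(expr.prop)
            filler = self.atom_for(expr.filler)
            self.ax.exist_rhs.add((cls, expr.prop, filler))
            self.ax.exist_lhs.add((expr.prop, filler, cls))
        elif isinstance(expr, Conjunction):
            atoms = []
            for part in expr.parts:
                if isinstance(part, Named):
                    self.check_class(part.id)
                    self.ax.atomic_subs.add((cls, part.id))
                    atoms.append(part.id)
                elif isinstance(part, Existential):
                    self.check_property(part.prop)
                    filler = self.atom_for(part.filler)
                    self.ax.exist_rhs.add((cls, part.prop, filler))
                    proxy = self.fresh(
                        f"some|{part.prop}|{canonical(part.filler)}"
                    )
                    self.ax.exist_lhs.add((part.prop, filler, proxy))
                    atoms.append(proxy)
                else:
                    raise TermforgeError(
                        f"unsupported conjunct in definition: {part!r}"
                    )
            self._fold_conjunction(atoms, cls)
        else:
            raise TermforgeError(f"unsupported expression form: {expr!r}")

    def _fold_conjunction(self, atoms: list[str], target: str) -> None:
        if len(atoms) == 1:
            self.ax.atomic_subs.add((atoms[0], target))
            return
        cur = atoms[0]
        for nxt in atoms[1:-1]:
            step = self.fresh(f"conj|{cur}|{nxt}")
            self.ax.conj_subs.add((cur, nxt, step))
            cur = step
        self.ax.conj_subs.add((cur, atoms[-1], target))

    def run(self, extra_defs=()) -> NormalizedAxiomSet:
        for term in self.ont.terms.values():
            if term.obsolete:
                continue
            for parent in term.told_parents:
                self.ax.atomic_subs.add((term.id, parent))
            for prop, target in term.relationships:
                self.check_property(prop)
                self.ax.exist_rhs.add((term.id, prop, target))
            if term.logical_def is not None:
                self.encode_equiv(term.id, term.logical_def)
        for prop in self.ont.properties.values():
            for parent in prop.parents:
                self.ax.role_subs.add((prop.id, parent))
            if prop.transitive:
                self.ax.role_trans.add(prop.id)
        for pair in self.ont.disjoint_pairs:
            a, b = sorted(pair)
            self.ax.bottom_subs.add((a, b))
        for cls, expr in extra_defs:
            self.ax.classes.add(cls)
            if not is_grounded(expr):
                raise TermforgeError(
                    f"expression for {cls} contains unresolved variables"
                )
            self.encode_equiv(cls, expr)
        return self.ax


def normalize(ontology: Ontology, extra_defs=()) -> NormalizedAxiomSet:
    """Translate an ontology (plus optional extra equivalence axioms,
    given as ``(class_id, expression)`` pairs) into EL normal form.

    Fresh intermediate names are deterministic functions of the source
    axiom, so repeated normalization of the same ontology yields the
    identical axiom set.
    """
    return _Normalizer(ontology).run(extra_defs)


# ---------------------------------------------------------------------------
# Saturation (completion rules)

def saturate(ax: NormalizedAxiomSet) -> SubsumptionClosure:
    """Run the EL completion rules to their least fixpoint.

    Rules (S = superclass sets, R = role links):

    * CR1  A' ∈ S(A), A' ⊑ B            ⇒ B ∈ S(A)
    * CR2  A1,A2 ∈ S(A), A1 ⊓ A2 ⊑ B    ⇒ B ∈ S(A)
    * CR3  A' ∈ S(A), A' ⊑ ∃r.B         ⇒ (A,B) ∈ R(r)
    * CR4  (A,B) ∈ R(r), B' ∈ S(B), ∃r.B' ⊑ C ⇒ C ∈ S(A)
    * CR5  (A,B) ∈ R(r), r ⊑ s          ⇒ (A,B) ∈ R(s)
    * CR6  trans(r), (A,B),(B,C) ∈ R(r) ⇒ (A,C) ∈ R(r)
    * CR⊥  ⊥ ∈ S(B), (A,B) ∈ R(r)       ⇒ ⊥ ∈ S(A)
    """
    classes = set(ax.classes) | set(ax.fresh_names)

    sub_idx = defaultdict(list)
    for a, b in ax.atomic_subs:
        sub_idx[a].append(b)
    conj_idx = defaultdict(list)
    all_conj = set(ax.conj_subs) | {(a, b, BOTTOM) for a, b in ax.bottom_subs}
    for a1, a2, b in all_conj:
        conj_idx[a1].append((a2, b))
        if a2 != a1:
            conj_idx[a2].append((a1, b))
    er_idx = defaultdict(list)
    for a, r, b in ax.exist_rhs:
        er_idx[a].append((r, b))
    el_by_filler = defaultdict(list)  # filler -> [(r, target)]
    el_by_role_filler = defaultdict(list)  # (r, filler) -> [target]
    for r, b, c in ax.exist_lhs:
        el_by_filler[b].append((r, c))
        el_by_role_filler[(r, b)].append(c)

    # reflexive-transitive role hierarchy closure
    super_roles: dict[str, set[str]] = {p: {p} for p in ax.properties}
    changed = True
    while changed:
        changed = False
        for r, s in ax.role_subs:
            before = len(super_roles[r])
            super_roles[r] |= super_roles.get(s, {s})
            changed = changed or len(super_roles[r]) != before
    trans = set(ax.role_trans)

    S: dict[str, set] = {c: set() for c in classes}
    succ: dict[str, dict] = defaultdict(lambda: defaultdict(set))
    pred: dict[str, dict] = defaultdict(lambda: defaultdict(set))
    agenda: deque = deque()

    def add_sub(a: str, x: str) -> None:
        if x not in S[a]:
            S[a].add(x)
            agenda.append(("s", a, x))

    def add_link(r: str, a: str, b: str) -> None:
        for s in super_roles.get(r, (r,)):
            if b not in succ[s][a]:
                succ[s][a].add(b)
                pred[s][b].add(a)
                agenda.append(("l", s, a, b))

    for c in classes:
        add_sub(c, c)
        add_sub(c, TOP)

    while agenda:
        ev = agenda.popleft()
        if ev[0] == "s":
            _, a, x = ev
            for b in sub_idx.get(x, ()):
                add_sub(a, b)
            sa = S[a]
            for other, b in conj_idx.get(x, ()):
                if other == x or other in sa:
                    add_sub(a, b)
            for r, b in er_idx.get(x, ()):
                add_link(r, a, b)
            # CR4, triggered by S(B) growing: x entered S(a); any link
            # (d, a) in R(r) with an axiom ∃r.x ⊑ c now yields c ∈ S(d)
            for r, c in el_by_filler.get(x, ()):
                for d in tuple(pred[r].get(a, ())):
                    add_sub(d, c)
            if x == BOTTOM:
                for r in list(pred):
                    for d in tuple(pred[r].get(a, ())):
                        add_sub(d, BOTTOM)
        else:
            _, r, a, b = ev
            # CR4, triggered by the new link
            for bp in tuple(S[b]):
                for c in el_by_role_filler.get((r, bp), ()):
                    add_sub(a, c)
            if r in trans:
                for c in tuple(succ[r].get(b, ())):
                    add_link(r, a, c)
                for z in tuple(pred[r].get(a, ())):
                    add_link(r, z, b)
            if BOTTOM in S[b]:
                add_sub(a, BOTTOM)

    R = {
        r: {(a, b) for a, targets in by_src.items() for b in targets}
        for r, by_src in succ.items()
    }
    unsat = {c for c in classes if BOTTOM in S[c]}
    return SubsumptionClosure(
        S=S, R=R, unsatisfiable=unsat, fresh_names=frozenset(ax.fresh_names)
    )


# ---------------------------------------------------------------------------
# Taxonomy construction

def _build_taxonomy(closure: SubsumptionClosure, named: set) -> Taxonomy:
    named = set(named)
    entailed = {
        a: (closure.S[a] & named) for a in named
    }  # reflexive supers restricted to the named signature
    group_of: dict[str, frozenset] = {}
    for a in named:
        if a in group_of:
            continue
        members = frozenset(
            b for b in entailed[a] if a in entailed[b]
        )
        for m in members:
            group_of[m] = members
    groups = sorted({g for g in group_of.values()}, key=min)
    reps = {g: min(g) for g in groups}

    strict: dict[frozenset, set] = {}
    for g in groups:
        rep = reps[g]
        strict[g] = {
            group_of[b] for b in entailed[rep] if group_of[b] is not group_of[rep]
        }
    direct_groups: dict[frozenset, set] = {}
    for g in groups:
        supers = strict[g]
        direct_groups[g] = {
            h for h in supers if not any(h in strict[k] for k in supers if k is not h)
        }

    direct_supers: dict[str, frozenset] = {}
    direct_subs_builder: dict[str, set] = {a: set() for a in named}
    for g in groups:
        parent_ids = frozenset(m for h in direct_groups[g] for m in h)
        for a in g:
            direct_supers[a] = parent_ids
        for h in direct_groups[g]:
            for p in h:
                direct_subs_builder[p] |= set(g)
    direct_subs = {a: frozenset(v) for a, v in direct_subs_builder.items()}
    return Taxonomy(
        direct_supers=direct_supers,
        direct_subs=direct_subs,
        equiv_groups=tuple(groups),
    )


def classify(ontology: Ontology) -> Taxonomy:
    """Full classification of the ontology (obsolete terms excluded)."""
    closure = saturate(normalize(ontology))
    named = {t.id for t in ontology.active_terms()}
    unsat = closure.unsatisfiable & named
    if unsat:
        raise IncoherentOntologyError(unsat)
    return _build_taxonomy(closure, named)


# ---------------------------------------------------------------------------
# Hypothetical placement

def place(ontology: Ontology, expr: Expr) -> PlacementResult:
    """Classify a hypothetical class defined by *expr* without asserting it.

    The candidate is added under a temporary identifier to a freshly
    normalized axiom set, the closure is saturated, and the verdict is
    read off; the ontology value itself is never modified.
    ``ontology_coherent`` reports whether the pre-existing named
    classes are all satisfiable — the sanity check done before any
    query is trusted.
    """
    if not is_grounded(expr):
        raise TermforgeError("placement expression contains unresolved variables")
    for cid in iter_named(expr):
        if cid not in ontology.terms:
            raise UnknownClassError(f"unknown class in expression: {cid}")
    for pid in iter_properties(expr):
        if pid not in ontology.properties:
            raise UnknownPropertyError(f"unknown relation in expression: {pid}")

    closure = saturate(normalize(ontology, extra_defs=[(TEMP_ID, expr)]))
    named = {t.id for t in ontology.active_terms()}
    coherent = not (closure.unsatisfiable & named)
    satisfiable = TEMP_ID not in closure.unsatisfiable
    if not satisfiable or not coherent:
        return PlacementResult(
            equivalents=frozenset(),
            direct_supers=frozenset(),
            direct_subs=frozenset(),
            satisfiable=satisfiable,
            ontology_coherent=coherent,
        )
    tax = _build_taxonomy(closure, named | {TEMP_ID})
    equivalents = tax.group_of(TEMP_ID) - {TEMP_ID}
    return PlacementResult(
        equivalents=frozenset(equivalents),
        direct_supers=frozenset(tax.direct_supers[TEMP_ID]),
        direct_subs=frozenset(tax.direct_subs[TEMP_ID]),
        satisfiable=True,
        ontology_coherent=True,
    )


def relation_rewrites_for(
    ontology: Ontology, placement: PlacementResult, new_id: str
) -> list[tuple[str, str, str]]:
    """is_a rewrites making the told graph match the inferred hierarchy.

    For every inferred direct subclass S of the new class, any told
    parent P of S that is an entailed superclass of the new class is
    replaced by the new class: the edge S→P becomes S→new_id.  After
    committing the new term together with these rewrites, the
    transitive reduction of the told is_a graph coincides with the
    batch-classified taxonomy.
    """
    if placement.equivalents:
        return []
    closure = saturate(normalize(ontology))
    supers_of_new: set[str] = set(placement.direct_supers)
    for d in placement.direct_supers:
        supers_of_new |= closure.S.get(d, set())
    supers_of_new -= {TOP, BOTTOM}

    rewrites = []
    for child in sorted(placement.direct_subs):
        term = ontology.terms.get(child)
        if term is None:
            continue
        for parent in sorted(term.told_parents):
            if parent in supers_of_new:
                rewrites.append((child, parent, new_id))
    return rewrites


def subclass_closure(ontology: Ontology, roots) -> set:
    """Roots plus every named class entailed below any root.

    Reflexive (each root is included); obsolete terms are excluded.
    """
    roots = set(roots)
    for r in roots:
        if r not in ontology.terms:
            raise UnknownClassError(f"unknown subset root: {r}")
    closure = saturate(normalize(ontology))
    out = set()
    for term in ontology.active_terms():
        supers = closure.S.get(term.id, set())
        if term.id in roots or (supers & roots):
            out.add(term.id)
    return out
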