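"""Reference structural subsumption checker.

This is an intentionally different algorithm from the completion-rule
reasoner in :mod:`termforge.reasoner`: instead of normalizing axioms
and saturating per-class superclass sets, it derives the subsumption
relation directly between the *expressions* occurring in the ontology
(a sequent-style closure over the subexpression set).  On acyclic
ontologies in the supported EL fragment the two must agree on every
named-class subsumption, which is exactly how the reasoner is
cross-validated in the test suite.

The derivation rules, applied in passes until nothing changes:

* reflexivity and transitivity of ⊑;
* told axioms: is_a links, relationship lines, and both directions of
  each genus-differentia equivalence;
* a conjunction is below each of its parts; anything below every part
  of a conjunction is below the conjunction;
* existential monotonicity: ``∃r.X ⊑ ∃s.Y`` when ``r ⊑* s`` and
  ``X ⊑ Y``;
* transitive-role composition: ``X ⊑ ∃t.Y`` and ``Y ⊑ ∃t.Z`` give
  ``X ⊑ ∃t.Z`` for transitive ``t``.

Disjointness is not interpreted here; the oracle targets coherent
ontologies (the random test ontologies carry no disjointness axioms).
"""

from __future__ import annotations

from .expressions import Conjunction, Existential, Expr, Named, canonical
from .obo import Ontology


def _role_supers(ont: Ontology) -> dict[str, set[str]]:
    supers = {p: {p} for p in ont.properties}
    changed = True
    while changed:
        changed = False
        for pid, prop in ont.properties.items():
            for parent in prop.parents:
                add = supers.get(parent, {parent}) - supers[pid]
                if add:
                    supers[pid] |= add
                    changed = True
    return supers


def _subexpressions(expr: Expr, acc: dict) -> None:
    acc[canonical(expr)] = expr
    if isinstance(expr, Existential):
        _subexpressions(expr.filler, acc)
    elif isinstance(expr, Conjunction):
        for p in expr.parts:
            _subexpressions(p, acc)


class StructuralReasoner:
    """Expression-level subsumption closure for one ontology."""

    def __init__(self, ontology: Ontology):
        self.ont = ontology
        self.role_supers = _role_supers(ontology)
        self.transitive = {
            p.id for p in ontology.properties.values() if p.transitive
        }
        self._build_universe()
        self._close()

    # -- universe -----------------------------------------------------
    def _build_universe(self) -> None:
        exprs: dict[str, Expr] = {}
        for term in self.ont.active_terms():
            _subexpressions(Named(term.id), exprs)
            for parent in term.told_parents:
                _subexpressions(Named(parent), exprs)
            for prop, target in term.relationships:
                _subexpressions(Existential(prop, Named(target)), exprs)
            if term.logical_def is not None:
                _subexpressions(term.logical_def, exprs)
        # lift every existential through the role hierarchy so that
        # hierarchy/transitivity compositions have a home in the universe
        for expr in list(exprs.values()):
            if isinstance(expr, Existential):
                for s in self.role_supers.get(expr.prop, {expr.prop}):
                    _subexpressions(Existential(s, expr.filler), exprs)
        # transitive roles compose links; make sure ∃t.F exists for every
        # filler F reachable at a transitive role t
        fillers = {
            canonical(e.filler): e.filler
            for e in exprs.values()
            if isinstance(e, Existential)
        }
        for t in self.transitive:
            for f in fillers.values():
                _subexpressions(Existential(t, f), exprs)
        self.exprs = exprs
        self.keys = sorted(exprs)

    # -- closure ------------------------------------------------------
    def _close(self) -> None:
        sup: dict[str, set[str]] = {k: {k} for k in self.keys}

        def add(x: str, y: str) -> bool:
            if y not in sup[x]:
                sup[x].add(y)
                return True
            return False

        # told edges
        for term in self.ont.active_terms():
            a = canonical(Named(term.id))
            for parent in term.told_parents:
                add(a, canonical(Named(parent)))
            for prop, target in term.relationships:
                add(a, canonical(Existential(prop, Named(target))))
            if term.logical_def is not None:
                d = canonical(term.logical_def)
                add(a, d)
                add(d, a)
        # a conjunction is below each part
        for k, expr in self.exprs.items():
            if isinstance(expr, Conjunction):
                for p in expr.parts:
                    add(k, canonical(p))

        conjs = [
            (k, [canonical(p) for p in e.parts])
            for k, e in self.exprs.items()
            if isinstance(e, Conjunction)
        ]
        exists = [
            (k, e.prop, canonical(e.filler))
            for k, e in self.exprs.items()
            if isinstance(e, Existential)
        ]

        changed = True
        while changed:
            changed = False
            # transitivity
            for x in self.keys:
                extra: set[str] = set()
                for y in sup[x]:
                    extra |= sup[y]
                if not extra <= sup[x]:
                    sup[x] |= extra
                    changed = True
            # conjunction introduction
            for ck, parts in conjs:
                for x in self.keys:
                    if ck not in sup[x] and all(p in sup[x] for p in parts):
                        sup[x].add(ck)
                        changed = True
            # existential monotonicity (role hierarchy included)
            for k1, r, f1 in exists:
                for k2, s, f2 in exists:
                    if k2 in sup[k1]:
                        continue
                    if s in self.role_supers.get(r, {r}) and f2 in sup[f1]:
                        sup[k1].add(k2)
                        changed = True
            # transitive-role composition
            for t in self.transitive:
                for x in self.keys:
                    for y in tuple(sup[x]):
                        ey = self.exprs[y]
                        if not (isinstance(ey, Existential) and ey.prop == t):
                            continue
                        fy = canonical(ey.filler)
                        for z in tuple(sup[fy]):
                            ez = self.exprs[z]
                            if isinstance(ez, Existential) and ez.prop == t:
                                composed = canonical(Existential(t, ez.filler))
                                if composed in sup and add(x, composed):
                                    changed = True
        self.sup = sup

    # -- queries ------------------------------------------------------
    def subsumes(self, sub_id: str, super_id: str) -> bool:
        """Is ``sub_id ⊑ super_id`` entailed?"""
        a, b = canonical(Named(sub_id)), canonical(Named(super_id))
        return a == b or b in self.sup.get(a, set())

    def named_subsumptions(self) -> set[tuple[str, str]]:
        """All strict entailed subsumptions between active named classes."""
        named = {t.id for t in self.ont.active_terms()}
        out = set()
        for a in named:
            ka = canonical(Named(a))
            for k in self.sup.get(ka, ()):
                e = self.exprs[k]
                if isinstance(e, Named) and e.id != a and e.id in named:
                    out.add((a, e.id))
        return out
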