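"""Class expressions for genus-differentia logical definitions.

The expression language is the EL fragment used by cross-product
definitions in OBO ontologies: named classes, existential restrictions
(``'has input' some CHEBI:27656``) and conjunctions.  Two extra leaf
kinds exist only inside template patterns and are never part of a
grounded definition: :class:`Variable` (a template input slot such as
``?X``) and :class:`LabelRef` (a class referenced by its quoted label,
resolved against the loaded ontology at instantiation time).

Conjunctions are flattened and their parts kept in a canonical order,
so structural equality is order-insensitive and serialization is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Union

Expr = Union["Named", "Existential", "Conjunction", "Variable", "LabelRef"]


@dataclass(frozen=True)
class Named:
    """A named class, identified by its CURIE."""

    id: str


@dataclass(frozen=True)
class Variable:
    """A template pattern variable, e.g. ``?X``."""

    name: str


@dataclass(frozen=True)
class LabelRef:
    """A class referenced by label, e.g. ``'catabolic process'``."""

    label: str


@dataclass(frozen=True)
class Existential:
    """An existential restriction ``prop some filler``."""

    prop: str
    filler: Expr


@dataclass(frozen=True)
class Conjunction:
    """A conjunction of two or more parts, flattened and canonically ordered."""

    parts: tuple

    def __post_init__(self):
        flat: list = []
        for p in self.parts:
            if isinstance(p, Conjunction):
                flat.extend(p.parts)
            else:
                flat.append(p)
        seen = {}
        for p in flat:
            seen.setdefault(canonical(p), p)
        ordered = tuple(seen[k] for k in sorted(seen))
        if len(ordered) < 2:
            raise ValueError("Conjunction needs at least two distinct parts")
        object.__setattr__(self, "parts", ordered)


def conjunction_of(*parts: Expr) -> Expr:
    """Build a conjunction, collapsing to the single part if only one remains."""
    flat: list = []
    for p in parts:
        if isinstance(p, Conjunction):
            flat.extend(p.parts)
        else:
            flat.append(p)
    uniq = {canonical(p): p for p in flat}
    if len(uniq) == 1:
        return next(iter(uniq.values()))
    return Conjunction(tuple(uniq.values()))


def canonical(expr: Expr) -> str:
    """Deterministic string form used for ordering, hashing and fresh names."""
    if isinstance(expr, Named):
        return expr.id
    if isinstance(expr, Variable):
        return "?" + expr.name
    if isinstance(expr, LabelRef):
        return "'" + expr.label + "'"
    if isinstance(expr, Existential):
        return f"some({expr.prop},{canonical(expr.filler)})"
    if isinstance(expr, Conjunction):
        return "and(" + ",".join(canonical(p) for p in expr.parts) + ")"
    raise TypeError(f"not a class expression: {expr!r}")


def iter_named(expr: Expr) -> Iterator[str]:
    """Yield every named-class id occurring in the expression."""
    if isinstance(expr, Named):
        yield expr.id
    elif isinstance(expr, Existential):
        yield from iter_named(expr.filler)
    elif isinstance(expr, Conjunction):
        for p in expr.parts:
            yield from iter_named(p)


def iter_properties(expr: Expr) -> Iterator[str]:
    """Yield every property id occurring in the expression."""
    if isinstance(expr, Existential):
        yield expr.prop
        yield from iter_properties(expr.filler)
    elif isinstance(expr, Conjunction):
        for p in expr.parts:
            yield from iter_properties(p)


def iter_variables(expr: Expr) -> Iterator[str]:
    """Yield every pattern variable name occurring in the expression."""
    if isinstance(expr, Variable):
        yield expr.name
    elif isinstance(expr, Existential):
        yield from iter_variables(expr.filler)
    elif isinstance(expr, Conjunction):
        for p in expr.parts:
            yield from iter_variables(p)


def is_grounded(expr: Expr) -> bool:
    """True iff the expression contains no Variable or LabelRef leaves."""
    if isinstance(expr, (Variable, LabelRef)):
        return False
    if isinstance(expr, Existential):
        return is_grounded(expr.filler)
    if isinstance(expr, Conjunction):
        return all(is_grounded(p) for p in expr.parts)
    return True


def substitute(expr: Expr, mapping: Mapping[str, Expr]) -> Expr:
    """Replace Variable leaves by name and LabelRef leaves by label.

    Variables are looked up under their name, label references under
    ``"'label'"`` keys (as produced by :func:`canonical`).
    """
    if isinstance(expr, Variable):
        return mapping.get(expr.name, expr)
    if isinstance(expr, LabelRef):
        return mapping.get(canonical(expr), expr)
    if isinstance(expr, Existential):
        return Existential(expr.prop, substitute(expr.filler, mapping))
    if isinstance(expr, Conjunction):
        return conjunction_of(*(substitute(p, mapping) for p in expr.parts))
    return expr


def expr_to_json(expr: Expr):
    """JSON-serializable structure for a grounded expression."""
    if isinstance(expr, Named):
        return {"named": expr.id}
    if isinstance(expr, Existential):
        return {"some": [expr.prop, expr_to_json(expr.filler)]}
    if isinstance(expr, Conjunction):
        return {"and": [expr_to_json(p) for p in expr.parts]}
    raise TypeError(f"cannot serialize non-grounded expression: {expr!r}")


def expr_from_json(data) -> Expr:
    if "named" in data:
        return Named(data["named"])
    if "some" in data:
        prop, filler = data["some"]
        return Existential(prop, expr_from_json(filler))
    if "and" in data:
        return Conjunction(tuple(expr_from_json(p) for p in data["and"]))
    raise ValueError(f"not an expression record: {data!r}")
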