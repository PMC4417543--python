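"""Subset-restricted term suggestion (autocompletion backend).

The index holds one entry per label and per synonym of every
non-obsolete class, pre-lowercased and tokenized, together with the
subset tags whose reasoner-derived closure contains the class.
Queries are ranked in four tiers — whole-label prefix, word prefix,
synonym prefix, substring — with ties broken by shorter label, then
class id, so the ranking is a deterministic total order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import TermforgeError, UnknownClassError
from .obo import Ontology
from .reasoner import subclass_closure

_WORD_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class IndexEntry:
    class_id: str
    label: str  # display label of the class
    text: str  # matched text (label itself or a synonym)
    source: str  # "label" | "synonym"
    text_lower: str
    tokens: tuple
    subsets: frozenset


@dataclass
class SuggestionIndex:
    entries: list
    subset_names: frozenset


def build_index(ontology: Ontology, subsets: dict | None = None) -> SuggestionIndex:
    """Build the suggestion index over one (possibly merged) ontology.

    *subsets* maps a subset name to its root class ids; membership is
    the reasoner's subclass closure of those roots, so a subset rooted
    in several ontologies simply lists several roots.
    """
    subsets = subsets or {}
    membership: dict[str, set] = {}
    for name, roots in subsets.items():
        roots = [roots] if isinstance(roots, str) else list(roots)
        for r in roots:
            if r not in ontology.terms:
                raise UnknownClassError(f"unknown subset root {r} ({name})")
        membership[name] = subclass_closure(ontology, roots)

    entries: list[IndexEntry] = []
    for term in sorted(ontology.active_terms(), key=lambda t: t.id):
        if term.stub or not term.label:
            continue
        tags = frozenset(n for n, members in membership.items()
                         if term.id in members)
        texts = [(term.label, "label")]
        texts += [(syn, "synonym") for syn, _scope in term.synonyms]
        for text, source in texts:
            lower = text.lower()
            entries.append(
                IndexEntry(
                    class_id=term.id,
                    label=term.label,
                    text=text,
                    source=source,
                    text_lower=lower,
                    tokens=tuple(_WORD_RE.findall(lower)),
                    subsets=tags,
                )
            )
    return SuggestionIndex(entries=entries, subset_names=frozenset(subsets))


def suggest(
    index: SuggestionIndex,
    query: str,
    subset: str | None = None,
    limit: int = 10,
) -> list[tuple[str, str, int]]:
    """Ranked suggestions ``(class_id, label, tier)`` for a query prefix.

    Tier 1: the whole label starts with the query; 2: some word of the
    label starts with it; 3: a synonym (whole or word) starts with it;
    4: the query occurs as a substring of label or synonym.  Lower
    tiers rank first.
    """
    if limit < 1:
        raise TermforgeError("limit must be >= 1")
    if subset is not None and subset not in index.subset_names:
        raise TermforgeError(f"unknown subset: {subset}")
    q = query.strip().lower()
    if not q:
        return []

    best: dict[str, tuple[int, str]] = {}  # class_id -> (tier, label)
    for entry in index.entries:
        if subset is not None and subset not in entry.subsets:
            continue
        if entry.source == "label":
            if entry.text_lower.startswith(q):
                tier = 1
            elif any(tok.startswith(q) for tok in entry.tokens):
                tier = 2
            elif q in entry.text_lower:
                tier = 4
            else:
                continue
        else:
            if entry.text_lower.startswith(q) or any(
                tok.startswith(q) for tok in entry.tokens
            ):
                tier = 3
            elif q in entry.text_lower:
                tier = 4
            else:
                continue
        cur = best.get(entry.class_id)
        if cur is None or tier < cur[0]:
            best[entry.class_id] = (tier, entry.label)

    ranked = sorted(
        ((cid, label, tier) for cid, (tier, label) in best.items()),
        key=lambda item: (item[2], len(item[1]), item[0]),
    )
    return ranked[:limit]
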