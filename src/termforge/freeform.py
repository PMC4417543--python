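"""Non-templated (free-form) class requests.

Free-form requests let experienced curators specify a class directly —
label, textual definition, told parents, plain relationships — without
an equivalence axiom, so the reasoner cannot police duplicates for
them.  Instead, the label is screened against every existing label and
synonym: an *exact* (case-folded) match always blocks, a *near* match
(edit distance ≤ 2, or one string containing the other with a length
difference ≤ 3) blocks unless the requester explicitly dismisses the
warning (``force``).  The canonical example: requesting ``omegasome``
warns about the existing ``megasome`` (distance 1); the two really are
different cell components, so the warning is dismissible.

Free-form requests share the identifier policy, queue and
review/commit machinery with templated requests, but are guarded by a
separate allow-list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .errors import SimilarLabelError, UnauthorizedError, UnknownClassError
from .obo import Ontology
from .pipeline import IdPolicy, RequestQueue, TermRequest, _now
from .templates import CandidateTerm

NEAR_DISTANCE = 2  # maximal edit distance reported as "near"
SUBSTRING_SLACK = 3  # maximal length difference for the containment rule


@dataclass(frozen=True)
class SimilarityWarning:
    existing_id: str
    existing_text: str
    matched_field: str  # "label" | "synonym"
    distance: int
    kind: str  # "exact" | "near"


@dataclass
class FreeformRequest:
    label: str
    definition: str
    def_xrefs: tuple = ()
    told_parents: frozenset = frozenset()
    relationships: frozenset = frozenset()
    synonyms: tuple = ()
    requester: str = ""
    namespace: str = ""

    def __post_init__(self):
        if not self.label:
            raise UnknownClassError("free-form request needs a non-empty label")
        self.told_parents = frozenset(self.told_parents)
        self.relationships = frozenset(
            tuple(r) for r in self.relationships
        )
        if not self.told_parents:
            raise UnknownClassError(
                "free-form request needs at least one told parent"
            )


def _edit_distance(a: str, b: str) -> int:
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def similar_label_warnings(label: str, ontology: Ontology) -> list:
    """Similarity warnings for a proposed label against all existing
    labels and synonyms (case-folded), sorted by distance then id."""
    query = label.casefold()
    warnings_: list[SimilarityWarning] = []
    for term in ontology.active_terms():
        if term.stub:
            continue
        candidates = [(term.label, "label")]
        candidates += [(syn, "synonym") for syn, _scope in term.synonyms]
        for text, source in candidates:
            if not text:
                continue
            other = text.casefold()
            distance = _edit_distance(query, other)
            is_substring = (
                (query in other or other in query)
                and abs(len(query) - len(other)) <= SUBSTRING_SLACK
            )
            if distance <= NEAR_DISTANCE or is_substring:
                warnings_.append(
                    SimilarityWarning(
                        existing_id=term.id,
                        existing_text=text,
                        matched_field=source,
                        distance=distance,
                        kind="exact" if distance == 0 else "near",
                    )
                )
    warnings_.sort(key=lambda w: (w.distance, w.existing_id, w.existing_text))
    return warnings_


def submit_freeform(
    request: FreeformRequest,
    queue: RequestQueue,
    policy: IdPolicy,
    ontology: Ontology,
    force: bool = False,
    allow_list=None,
    clock=_now,
) -> TermRequest:
    """Validate and queue a free-form class request.

    Exact label collisions always block; near collisions block unless
    *force* dismisses them.  The queued candidate carries told parents
    and relationships but no equivalence axiom.
    """
    if allow_list is not None and request.requester not in allow_list:
        raise UnauthorizedError(
            f"{request.requester} is not permitted to submit free-form requests"
        )
    for parent in sorted(request.told_parents):
        if parent not in ontology.terms:
            raise UnknownClassError(f"unknown parent: {parent}")
    for prop, target in sorted(request.relationships):
        if prop not in ontology.properties:
            raise UnknownClassError(f"unknown relation: {prop}")
        if target not in ontology.terms:
            raise UnknownClassError(f"unknown relationship target: {target}")

    warnings_ = similar_label_warnings(request.label, ontology)
    exact = [w for w in warnings_ if w.kind == "exact"]
    if exact:
        raise SimilarLabelError(exact)
    if warnings_ and not force:
        raise SimilarLabelError(warnings_)

    now = clock()
    candidate = CandidateTerm(
        label=request.label,
        definition=request.definition,
        def_xrefs=tuple(request.def_xrefs),
        synonyms=tuple(request.synonyms),
        logical_def=None,
        namespace=request.namespace,
        created_by=request.requester,
        creation_date=now,
        told_parents=tuple(sorted(request.told_parents)),
        relationships=tuple(sorted(request.relationships)),
    )
    assigned = policy.next_id(ontology)
    term_request = TermRequest(
        request_id=queue.next_request_id(),
        candidate=candidate,
        assigned_id=assigned,
        placement=None,
        rewrites=(),
        requester=request.requester,
        submitted_at=now,
        template_name="",
    )
    queue._append({"event": "submit", "request": term_request.to_json()})
    return queue.get(term_request.request_id)
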