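"""Request lifecycle: generation, identifier allocation, review queue,
and per-request commit back to the ontology file.

Identifiers are permanent from the moment of submission: a request
that turns out to be unwanted is *obsoleted*, never deleted, so its
identifier stays resolvable (it is committed as an obsolete stub
term).  The queue is an append-only JSON-lines event log; replaying
the log reconstructs the exact queue state, which is also how the
queue survives being closed and reopened.

Commit processes each request separately against a freshly reloaded
ontology file (the clean-checkout discipline): the quick checks are
re-run — identifier unused, still no equivalent named class, still
satisfiable — the term and its is_a rewrites are applied, the file is
rewritten atomically, and one changelog entry is appended.  A failing
request aborts only itself.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import (
    DuplicateClassError,
    IdRangeExhaustedError,
    QueueStateError,
    TermforgeError,
    UnauthorizedError,
    UnsatisfiableCandidateError,
    IncoherentOntologyError,
)
from .expressions import expr_from_json, expr_to_json
from .obo import Ontology, TermRecord, apply_new_term, parse_obo, write_obo
from .reasoner import PlacementResult, place, relation_rewrites_for
from .templates import Binding, CandidateTerm, TemplateSpec, instantiate

PENDING = "pending"
APPROVED = "approved"
COMMITTED = "committed"
OBSOLETED = "obsoleted"

_EDITABLE = ("label", "definition", "synonyms")


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# Identifier policy

@dataclass
class IdPolicy:
    """Customizable identifier pattern and range, with persisted state."""

    prefix: str
    width: int
    range_start: int
    range_end: int
    state_path: Path | None = None
    allocated: set = field(default_factory=set)

    def __post_init__(self):
        if self.range_start > self.range_end:
            raise TermforgeError("identifier range is empty")
        self.state_path = Path(self.state_path) if self.state_path else None
        if self.state_path and self.state_path.exists():
            data = json.loads(self.state_path.read_text())
            self.allocated |= set(data.get("allocated", []))
        bad = {n for n in self.allocated
               if not self.range_start <= n <= self.range_end}
        if bad:
            raise TermforgeError(f"allocated ids outside range: {sorted(bad)}")

    def format(self, number: int) -> str:
        return f"{self.prefix}:{number:0{self.width}d}"

    def _persist(self) -> None:
        if self.state_path:
            _atomic_write(
                self.state_path,
                json.dumps({"allocated": sorted(self.allocated)}) + "\n",
            )

    def next_id(self, ontology: Ontology | None = None) -> str:
        """Allocate the smallest free identifier in range.

        Ids already present in the loaded ontology count as allocated.
        The allocation is persisted before the id is returned.
        """
        for n in range(self.range_start, self.range_end + 1):
            if n in self.allocated:
                continue
            cid = self.format(n)
            if ontology is not None and cid in ontology.terms:
                self.allocated.add(n)  # discovered as taken; remember it
                continue
            self.allocated.add(n)
            self._persist()
            return cid
        raise IdRangeExhaustedError(
            f"no free identifier in {self.format(self.range_start)}"
            f"..{self.format(self.range_end)}"
        )


def next_id(policy: IdPolicy, ontology: Ontology | None = None) -> str:
    return policy.next_id(ontology)


# ---------------------------------------------------------------------------
# Requests and queue

@dataclass
class TermRequest:
    request_id: int
    candidate: CandidateTerm
    assigned_id: str
    placement: PlacementResult | None
    rewrites: tuple
    requester: str
    submitted_at: str
    status: str = PENDING
    review_note: str = ""
    template_name: str = ""

    def to_json(self) -> dict:
        cand = {
            "label": self.candidate.label,
            "definition": self.candidate.definition,
            "def_xrefs": list(self.candidate.def_xrefs),
            "synonyms": [list(s) for s in self.candidate.synonyms],
            "namespace": self.candidate.namespace,
            "created_by": self.candidate.created_by,
            "creation_date": self.candidate.creation_date,
            "told_parents": list(self.candidate.told_parents),
            "relationships": [list(r) for r in self.candidate.relationships],
            "logical_def": (
                expr_to_json(self.candidate.logical_def)
                if self.candidate.logical_def is not None
                else None
            ),
        }
        placement = None
        if self.placement is not None:
            placement = {
                "equivalents": sorted(self.placement.equivalents),
                "direct_supers": sorted(self.placement.direct_supers),
                "direct_subs": sorted(self.placement.direct_subs),
                "satisfiable": self.placement.satisfiable,
                "ontology_coherent": self.placement.ontology_coherent,
            }
        return {
            "request_id": self.request_id,
            "candidate": cand,
            "assigned_id": self.assigned_id,
            "placement": placement,
            "rewrites": [list(r) for r in self.rewrites],
            "requester": self.requester,
            "submitted_at": self.submitted_at,
            "template_name": self.template_name,
        }

    @classmethod
    def from_json(cls, data: dict) -> "TermRequest":
        c = data["candidate"]
        candidate = CandidateTerm(
            label=c["label"],
            definition=c["definition"],
            def_xrefs=tuple(c["def_xrefs"]),
            synonyms=tuple(tuple(s) for s in c["synonyms"]),
            logical_def=(
                expr_from_json(c["logical_def"])
                if c["logical_def"] is not None
                else None
            ),
            namespace=c["namespace"],
            created_by=c["created_by"],
            creation_date=c["creation_date"],
            told_parents=tuple(c.get("told_parents", ())),
            relationships=tuple(tuple(r) for r in c.get("relationships", ())),
        )
        p = data.get("placement")
        placement = None
        if p is not None:
            placement = PlacementResult(
                equivalents=frozenset(p["equivalents"]),
                direct_supers=frozenset(p["direct_supers"]),
                direct_subs=frozenset(p["direct_subs"]),
                satisfiable=p["satisfiable"],
                ontology_coherent=p["ontology_coherent"],
            )
        return cls(
            request_id=data["request_id"],
            candidate=candidate,
            assigned_id=data["assigned_id"],
            placement=placement,
            rewrites=tuple(tuple(r) for r in data["rewrites"]),
            requester=data["requester"],
            submitted_at=data["submitted_at"],
            template_name=data.get("template_name", ""),
        )


class RequestQueue:
    """Append-only, file-backed request queue (JSON lines event log)."""

    def __init__(self, path):
        self.path = Path(path)
        self.requests: dict[int, TermRequest] = {}
        if self.path.exists():
            self._replay()

    def _replay(self) -> None:
        for lineno, line in enumerate(self.path.read_text().splitlines(), 1):
            line = line.strip()
            if not line:
                continue
            try:
                event = json.loads(line)
            except json.JSONDecodeError as exc:
                raise QueueStateError(
                    f"corrupt queue line {lineno}: {exc}"
                ) from exc
            self._apply(event)

    def _apply(self, event: dict) -> None:
        kind = event["event"]
        if kind == "submit":
            req = TermRequest.from_json(event["request"])
            if req.request_id in self.requests:
                raise QueueStateError(
                    f"duplicate request id in log: {req.request_id}"
                )
            self.requests[req.request_id] = req
        elif kind == "review":
            req = self.requests[event["request_id"]]
            action = event["action"]
            if action == "approve":
                edits = event.get("edits") or {}
                if "label" in edits:
                    req.candidate = replace(req.candidate, label=edits["label"])
                if "definition" in edits:
                    req.candidate = replace(
                        req.candidate, definition=edits["definition"]
                    )
                if "synonyms" in edits:
                    req.candidate = replace(
                        req.candidate,
                        synonyms=tuple(tuple(s) for s in edits["synonyms"]),
                    )
                req.status = APPROVED
            elif action == "obsolete":
                req.status = OBSOLETED
            req.review_note = event.get("note", "")
        elif kind == "committed":
            req = self.requests[event["request_id"]]
            if req.status == APPROVED:
                req.status = COMMITTED
        else:
            raise QueueStateError(f"unknown queue event: {kind}")

    def _append(self, event: dict) -> None:
        self._apply(event)
        with self.path.open("a") as fh:
            fh.write(json.dumps(event, sort_keys=True) + "\n")
            fh.flush()
            os.fsync(fh.fileno())

    # -- queries ------------------------------------------------------
    def next_request_id(self) -> int:
        return max(self.requests, default=0) + 1

    def get(self, request_id: int) -> TermRequest:
        try:
            return self.requests[request_id]
        except KeyError:
            raise QueueStateError(f"unknown request id: {request_id}") from None

    def by_status(self, *statuses) -> list:
        return sorted(
            (r for r in self.requests.values() if r.status in statuses),
            key=lambda r: r.request_id,
        )

    def find_by_assigned_id(self, class_id: str) -> TermRequest | None:
        for req in self.requests.values():
            if req.assigned_id == class_id:
                return req
        return None


# ---------------------------------------------------------------------------
# Operations

def submit(
    template: TemplateSpec,
    binding: Binding,
    requester: str,
    ontology: Ontology,
    policy: IdPolicy,
    queue: RequestQueue,
    allow_list=None,
    clock=_now,
    closures: dict | None = None,
) -> TermRequest:
    """Generate, reason about, and queue a templated class request.

    Fails on validation errors, on a duplicate (an equivalent named
    class already exists — the error names it), on an unsatisfiable
    candidate, and on an incoherent ontology.  On success the request
    is pending with a freshly allocated permanent identifier.
    """
    if allow_list is not None and requester not in allow_list:
        raise UnauthorizedError(
            f"{requester} is not permitted to submit template requests"
        )
    now = clock()
    candidate = instantiate(
        template, binding, ontology,
        created_by=requester, creation_date=now, closures=closures,
    )
    placement = place(ontology, candidate.logical_def)
    if not placement.ontology_coherent:
        raise IncoherentOntologyError(set())
    if not placement.satisfiable:
        raise UnsatisfiableCandidateError(
            f"candidate {candidate.label!r} is unsatisfiable"
        )
    if placement.equivalents:
        raise DuplicateClassError(placement.equivalents)

    assigned = policy.next_id(ontology)
    rewrites = relation_rewrites_for(ontology, placement, assigned)
    request = TermRequest(
        request_id=queue.next_request_id(),
        candidate=candidate,
        assigned_id=assigned,
        placement=placement,
        rewrites=tuple(rewrites),
        requester=requester,
        submitted_at=now,
        template_name=template.name,
    )
    queue._append({"event": "submit", "request": request.to_json()})
    return queue.get(request.request_id)


def status(queue: RequestQueue, class_id: str) -> str:
    """``approved`` | ``pending`` | ``unknown`` for a class identifier."""
    req = queue.find_by_assigned_id(class_id)
    if req is None:
        return "unknown"
    if req.status in (APPROVED, COMMITTED):
        return "approved"
    if req.status == PENDING:
        return "pending"
    return "unknown"


def review(
    queue: RequestQueue,
    request_id: int,
    action: str,
    edits: dict | None = None,
    note: str = "",
) -> TermRequest:
    """Approve (optionally with textual edits) or obsolete a request.

    There is no reject: a permanent identifier has already been
    handed out, so the only way to refuse a request is obsoletion.
    Edits may touch only label, definition and synonyms — the logical
    definition is immutable at review time.
    """
    req = queue.get(request_id)
    if action == "approve":
        if req.status != PENDING:
            raise QueueStateError(
                f"request {request_id} is {req.status}; only pending "
                "requests can be approved"
            )
        if edits:
            illegal = set(edits) - set(_EDITABLE)
            if illegal:
                raise QueueStateError(
                    f"review edits may touch only {_EDITABLE}; got "
                    f"{sorted(illegal)}"
                )
        queue._append(
            {"event": "review", "request_id": request_id, "action": "approve",
             "edits": edits or {}, "note": note}
        )
    elif action == "obsolete":
        if req.status not in (PENDING, APPROVED):
            raise QueueStateError(
                f"request {request_id} is {req.status}; cannot obsolete"
            )
        queue._append(
            {"event": "review", "request_id": request_id, "action": "obsolete",
             "note": note}
        )
    else:
        raise QueueStateError(f"unknown review action: {action}")
    return queue.get(request_id)


@dataclass
class CommitEntry:
    request_id: int
    assigned_id: str
    action: str  # "added" | "obsoleted" | "failed"
    ok: bool
    message: str = ""


@dataclass
class CommitReport:
    entries: list

    @property
    def succeeded(self):
        return [e for e in self.entries if e.ok]

    @property
    def failed(self):
        return [e for e in self.entries if not e.ok]


def _term_from_candidate(candidate: CandidateTerm, assigned_id: str,
                         told_parents) -> TermRecord:
    return TermRecord(
        id=assigned_id,
        label=candidate.label,
        definition=candidate.definition,
        def_xrefs=candidate.def_xrefs,
        synonyms=candidate.synonyms,
        namespace=candidate.namespace,
        told_parents=set(told_parents),
        relationships=set(candidate.relationships),
        logical_def=candidate.logical_def,
        created_by=candidate.created_by,
        creation_date=candidate.creation_date,
    )


def commit(
    queue: RequestQueue,
    ontology_path,
    request_ids,
    changelog_path=None,
    external_prefixes=(),
    clock=_now,
) -> CommitReport:
    """Commit approved/obsoleted requests to the ontology file, one by one.

    Requests are processed in request-id order, each against a freshly
    reloaded ontology.  Quick checks re-run before every write; a
    failing request is recorded in the report and skipped, later
    requests still proceed.
    """
    ontology_path = Path(ontology_path)
    changelog_path = Path(changelog_path) if changelog_path else None
    entries: list[CommitEntry] = []

    for request_id in sorted(request_ids):
        req = queue.get(request_id)
        if req.status not in (APPROVED, OBSOLETED):
            entries.append(CommitEntry(
                request_id, req.assigned_id, "failed", False,
                f"request is {req.status}; only approved or obsoleted "
                "requests can be committed",
            ))
            continue

        ont = parse_obo(ontology_path.read_text(), external_prefixes)
        if req.assigned_id in ont.terms and not ont.terms[req.assigned_id].stub:
            entries.append(CommitEntry(
                request_id, req.assigned_id, "failed", False,
                f"identifier {req.assigned_id} already present in ontology",
            ))
            continue

        if req.status == OBSOLETED:
            stub = TermRecord(
                id=req.assigned_id,
                label=req.candidate.label,
                namespace=req.candidate.namespace,
                obsolete=True,
                comment=req.review_note or "obsoleted at review",
                created_by=req.candidate.created_by,
                creation_date=req.candidate.creation_date,
            )
            new_ont = apply_new_term(ont, stub)
            _atomic_write(ontology_path, write_obo(new_ont))
            _log_commit(changelog_path, clock(), req, "obsoleted")
            queue._append({"event": "committed", "request_id": request_id})
            entries.append(CommitEntry(
                request_id, req.assigned_id, "obsoleted", True,
                "committed as obsolete stub",
            ))
            continue

        candidate = req.candidate
        if candidate.logical_def is not None:
            placement = place(ont, candidate.logical_def)
            if not placement.satisfiable:
                entries.append(CommitEntry(
                    request_id, req.assigned_id, "failed", False,
                    "candidate became unsatisfiable",
                ))
                continue
            if placement.equivalents:
                entries.append(CommitEntry(
                    request_id, req.assigned_id, "failed", False,
                    "stale duplicate: now equivalent to "
                    + ", ".join(sorted(placement.equivalents)),
                ))
                continue
            told_parents = placement.direct_supers
            rewrites = relation_rewrites_for(ont, placement, req.assigned_id)
        else:
            missing = [p for p in candidate.told_parents if p not in ont.terms]
            if missing:
                entries.append(CommitEntry(
                    request_id, req.assigned_id, "failed", False,
                    f"parent(s) no longer present: {', '.join(missing)}",
                ))
                continue
            told_parents = candidate.told_parents
            rewrites = ()

        if any(t.label == candidate.label and not t.obsolete and not t.stub
               for t in ont.terms.values()):
            entries.append(CommitEntry(
                request_id, req.assigned_id, "failed", False,
                f"label {candidate.label!r} already in use",
            ))
            continue

        term = _term_from_candidate(candidate, req.assigned_id, told_parents)
        new_ont = apply_new_term(ont, term, rewrites)
        _atomic_write(ontology_path, write_obo(new_ont))
        _log_commit(changelog_path, clock(), req, "added")
        queue._append({"event": "committed", "request_id": request_id})
        entries.append(CommitEntry(
            request_id, req.assigned_id, "added", True,
            f"added with parents {', '.join(sorted(told_parents)) or '(root)'}",
        ))

    return CommitReport(entries)


def _log_commit(changelog_path, timestamp, req, action) -> None:
    if changelog_path is None:
        return
    line = "\t".join(
        [timestamp, str(req.request_id), req.assigned_id, action,
         req.candidate.label]
    )
    with changelog_path.open("a") as fh:
        fh.write(line + "\n")
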