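"""In-memory ontology model plus reader/writer for an OBO 1.4 subset.

Supported tags
--------------
Header: ``format-version``, ``ontology``.
``[Term]``: ``id, name, namespace, def, comment, synonym, is_a,
relationship, intersection_of, is_obsolete, created_by, creation_date``.
``[Typedef]``: ``id, name, is_a, is_transitive``.

Any other tag line is preserved verbatim (per stanza, in order) and
re-emitted on serialization, so documents using a richer dialect
round-trip losslessly at the text level even though only the supported
tags are interpreted.

A ``[Term]`` stanza with exactly one genus ``intersection_of: <class>``
line and one or more differentia ``intersection_of: <rel> <class>``
lines is interpreted as a genus-differentia equivalence axiom and
stored as a :class:`~termforge.expressions.Conjunction`.

Serialization is canonical: stanzas sorted by id, tags in a fixed
order, set-valued tags sorted — writing the same ontology value twice
yields byte-identical text, and ``parse_obo(write_obo(o))`` is
structurally equal to ``o``.
"""

from __future__ import annotations

import copy
import re
import warnings
from dataclasses import dataclass, field

from .errors import (
    DuplicateIdError,
    OboLoadWarning,
    OboParseError,
    TermforgeError,
    UnknownClassError,
)
from .expressions import Conjunction, Existential, Expr, Named, iter_named

SYNONYM_SCOPES = ("EXACT", "BROAD", "NARROW", "RELATED")

_CURIE_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_.-]*):(\S+)$")


def check_curie(value: str) -> tuple[str, str]:
    """Split a CURIE into (prefix, local id); raise on malformed input."""
    m = _CURIE_RE.match(value)
    if not m:
        raise TermforgeError(f"malformed CURIE: {value!r}")
    return m.group(1), m.group(2)


def curie_prefix(value: str) -> str:
    return check_curie(value)[0]


@dataclass
class PropertyRecord:
    """An object property (OBO Typedef).

    Property ids may be label-like tokens such as ``has_input`` rather
    than CURIEs, mirroring common OBO usage.
    """

    id: str
    label: str = ""
    parents: set = field(default_factory=set)
    transitive: bool = False
    extra_lines: tuple = ()


@dataclass
class TermRecord:
    """A single ontology class (OBO Term stanza)."""

    id: str
    label: str = ""
    definition: str = ""
    def_xrefs: tuple = ()
    synonyms: tuple = ()  # tuples of (text, scope), kept sorted
    namespace: str = ""
    told_parents: set = field(default_factory=set)
    relationships: set = field(default_factory=set)  # of (property, target)
    logical_def: Expr | None = None
    obsolete: bool = False
    comment: str = ""
    created_by: str = ""
    creation_date: str = ""
    stub: bool = False  # auto-created placeholder for an external reference
    extra_lines: tuple = ()

    def __post_init__(self):
        self.def_xrefs = tuple(self.def_xrefs)
        self.synonyms = tuple(sorted(self.synonyms))
        self.told_parents = set(self.told_parents)
        self.relationships = set(self.relationships)


@dataclass
class Ontology:
    """A loaded ontology: terms, properties and disjointness pairs."""

    terms: dict = field(default_factory=dict)  # ClassId -> TermRecord
    properties: dict = field(default_factory=dict)  # PropertyId -> PropertyRecord
    disjoint_pairs: set = field(default_factory=set)  # frozenset pairs of ClassId
    format_tag: str = ""
    header_extras: tuple = ()

    def copy(self) -> "Ontology":
        return copy.deepcopy(self)

    def label_of(self, class_id: str) -> str:
        term = self.terms.get(class_id)
        return term.label if term else class_id

    def term_by_label(self, label: str) -> TermRecord | None:
        for term in self.terms.values():
            if not term.obsolete and term.label == label:
                return term
        return None

    def active_terms(self):
        return (t for t in self.terms.values() if not t.obsolete)

    def merge(self, other: "Ontology") -> None:
        """Fold another ontology into this one (multi-ontology workspace).

        A real term always replaces a stub for the same id; two real
        terms with the same id are an error.
        """
        for cid, term in other.terms.items():
            mine = self.terms.get(cid)
            if mine is None or (mine.stub and not term.stub):
                self.terms[cid] = copy.deepcopy(term)
            elif not mine.stub and not term.stub:
                raise DuplicateIdError(f"duplicate term id across ontologies: {cid}")
        for pid, prop in other.properties.items():
            self.properties.setdefault(pid, copy.deepcopy(prop))
        self.disjoint_pairs |= other.disjoint_pairs


# ---------------------------------------------------------------------------
# Parsing

_QUOTED_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*(.*)$')

_TERM_TAGS = {
    "id", "name", "namespace", "def", "comment", "synonym", "is_a",
    "relationship", "intersection_of", "is_obsolete", "created_by",
    "creation_date",
}
_TYPEDEF_TAGS = {"id", "name", "is_a", "is_transitive"}
_HEADER_TAGS = {"format-version", "ontology"}


def _unescape(text: str) -> str:
    return text.replace('\\"', '"').replace("\\\\", "\\")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _strip_trailing_comment(value: str) -> str:
    # OBO allows a trailing " ! human readable comment" after ids
    idx = value.find(" ! ")
    if idx >= 0:
        value = value[:idx]
    return value.strip()


def _parse_quoted(value: str, lineno: int):
    m = _QUOTED_RE.match(value.strip())
    if not m:
        raise OboParseError(f"expected quoted string: {value!r}", lineno)
    return _unescape(m.group(1)), m.group(2).strip()


def parse_obo(text: str, external_prefixes=()) -> Ontology:
    """Parse an OBO document into an :class:`Ontology`.

    References to ids whose prefix is listed in *external_prefixes*
    auto-create flagged stub terms (mirroring cross-ontology loading);
    any other dangling reference is a load-time error.
    """
    external_prefixes = frozenset(external_prefixes)
    ont = Ontology()

    stanza_type: str | None = None  # None = header
    stanza: dict | None = None
    stanza_line = 0

    def flush():
        nonlocal stanza
        if stanza_type is None or stanza is None:
            return
        if "id" not in stanza:
            raise OboParseError(f"stanza without id", stanza_line)
        sid = stanza["id"]
        if stanza_type == "Term":
            check_curie(sid)
            if sid in ont.terms:
                raise OboParseError(f"duplicate term id: {sid}", stanza_line)
            genus = stanza.get("genus", [])
            diffs = stanza.get("diffs", [])
            logical_def = None
            if genus or diffs:
                if len(genus) != 1 or not diffs:
                    raise OboParseError(
                        "intersection_of must give exactly one genus and at "
                        f"least one differentia ({sid})",
                        stanza_line,
                    )
                logical_def = Conjunction(
                    (Named(genus[0]),)
                    + tuple(Existential(p, Named(f)) for p, f in diffs)
                )
            term = TermRecord(
                id=sid,
                label=stanza.get("name", ""),
                definition=stanza.get("def", ""),
                def_xrefs=tuple(stanza.get("def_xrefs", ())),
                synonyms=tuple(stanza.get("synonyms", ())),
                namespace=stanza.get("namespace", ""),
                told_parents=set(stanza.get("is_a", ())),
                relationships=set(stanza.get("relationships", ())),
                logical_def=logical_def,
                obsolete=stanza.get("obsolete", False),
                comment=stanza.get("comment", ""),
                created_by=stanza.get("created_by", ""),
                creation_date=stanza.get("creation_date", ""),
                extra_lines=tuple(stanza.get("extras", ())),
            )
            if term.obsolete and (
                term.told_parents or term.relationships or term.logical_def
            ):
                raise OboParseError(
                    f"obsolete term {sid} must not carry is_a, relationship "
                    "or intersection_of lines",
                    stanza_line,
                )
            ont.terms[sid] = term
        else:
            if sid in ont.properties:
                raise OboParseError(f"duplicate typedef id: {sid}", stanza_line)
            ont.properties[sid] = PropertyRecord(
                id=sid,
                label=stanza.get("name", ""),
                parents=set(stanza.get("is_a", ())),
                transitive=stanza.get("transitive", False),
                extra_lines=tuple(stanza.get("extras", ())),
            )
        stanza = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip() or line.lstrip().startswith("!"):
            continue
        if line.startswith("["):
            flush()
            if line == "[Term]":
                stanza_type = "Term"
            elif line == "[Typedef]":
                stanza_type = "Typedef"
            else:
                raise OboParseError(f"unknown stanza type: {line}", lineno)
            stanza = {}
            stanza_line = lineno
            continue
        if ":" not in line:
            raise OboParseError(f"not a tag-value line: {line!r}", lineno)
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = value.strip()

        if stanza_type is None:
            if tag == "format-version":
                pass  # accepted; always re-emitted as 1.4
            elif tag == "ontology":
                ont.format_tag = value
            else:
                ont.header_extras = ont.header_extras + (line,)
            continue

        assert stanza is not None
        known = _TERM_TAGS if stanza_type == "Term" else _TYPEDEF_TAGS
        if tag not in known:
            stanza.setdefault("extras", []).append(line)
            continue
        if tag == "id":
            stanza["id"] = _strip_trailing_comment(value)
        elif tag == "name":
            stanza["name"] = value
        elif tag == "namespace":
            stanza["namespace"] = value
        elif tag == "comment":
            stanza["comment"] = value
        elif tag == "created_by":
            stanza["created_by"] = value
        elif tag == "creation_date":
            stanza["creation_date"] = value
        elif tag == "def":
            text_part, rest = _parse_quoted(value, lineno)
            stanza["def"] = text_part
            xrefs: list[str] = []
            if rest.startswith("[") and rest.endswith("]"):
                inner = rest[1:-1].strip()
                if inner:
                    xrefs = [x.strip() for x in inner.split(",")]
            stanza["def_xrefs"] = xrefs
        elif tag == "synonym":
            text_part, rest = _parse_quoted(value, lineno)
            scope = rest.split()[0] if rest else "RELATED"
            if scope.startswith("["):
                scope = "RELATED"
            if scope not in SYNONYM_SCOPES:
                raise OboParseError(f"unknown synonym scope: {scope}", lineno)
            stanza.setdefault("synonyms", []).append((text_part, scope))
        elif tag == "is_a":
            stanza.setdefault("is_a", []).append(_strip_trailing_comment(value))
        elif tag == "relationship":
            parts = _strip_trailing_comment(value).split()
            if len(parts) != 2:
                raise OboParseError(f"malformed relationship line: {value!r}", lineno)
            stanza.setdefault("relationships", []).append((parts[0], parts[1]))
        elif tag == "intersection_of":
            parts = _strip_trailing_comment(value).split()
            if len(parts) == 1:
                stanza.setdefault("genus", []).append(parts[0])
            elif len(parts) == 2:
                stanza.setdefault("diffs", []).append((parts[0], parts[1]))
            else:
                raise OboParseError(
                    f"malformed intersection_of line: {value!r}", lineno
                )
        elif tag == "is_obsolete":
            stanza["obsolete"] = value.lower() == "true"
        elif tag == "is_transitive":
            stanza["transitive"] = value.lower() == "true"
    flush()

    _resolve_references(ont, external_prefixes)
    _check_label_uniqueness(ont)
    return ont


def _resolve_references(ont: Ontology, external_prefixes: frozenset) -> None:
    def resolve_class(cid: str, context: str) -> None:
        if cid in ont.terms:
            if ont.terms[cid].obsolete:
                warnings.warn(
                    f"{context} references obsolete term {cid}", OboLoadWarning
                )
            return
        prefix = check_curie(cid)[0]
        if prefix in external_prefixes:
            ont.terms[cid] = TermRecord(id=cid, label=cid, stub=True)
        else:
            raise OboParseError(f"dangling reference to {cid} from {context}")

    def resolve_property(pid: str, context: str) -> None:
        if pid not in ont.properties:
            raise OboParseError(f"unknown relation {pid} referenced from {context}")

    for term in list(ont.terms.values()):
        for parent in term.told_parents:
            resolve_class(parent, term.id)
        for prop, target in term.relationships:
            resolve_property(prop, term.id)
            resolve_class(target, term.id)
        if term.logical_def is not None:
            from .expressions import iter_properties

            for cid in iter_named(term.logical_def):
                resolve_class(cid, term.id)
            for pid in iter_properties(term.logical_def):
                resolve_property(pid, term.id)
    for prop in ont.properties.values():
        for parent in prop.parents:
            if parent not in ont.properties:
                raise OboParseError(
                    f"dangling sub-property reference to {parent} from {prop.id}"
                )


def _check_label_uniqueness(ont: Ontology) -> None:
    seen: dict[str, str] = {}
    for term in ont.terms.values():
        if term.obsolete or term.stub or not term.label:
            continue
        if term.label in seen:
            raise OboParseError(
                f"duplicate label {term.label!r} on {seen[term.label]} and {term.id}"
            )
        seen[term.label] = term.id


# ---------------------------------------------------------------------------
# Serialization

def write_obo(ont: Ontology) -> str:
    """Serialize an ontology canonically; pure function of the value."""
    lines: list[str] = ["format-version: 1.4"]
    if ont.format_tag:
        lines.append(f"ontology: {ont.format_tag}")
    lines.extend(ont.header_extras)

    for cid in sorted(t for t, rec in ont.terms.items() if not rec.stub):
        term = ont.terms[cid]
        lines.append("")
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        if term.label:
            lines.append(f"name: {term.label}")
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        if term.definition or term.def_xrefs:
            xrefs = ", ".join(term.def_xrefs)
            lines.append(f'def: "{_escape(term.definition)}" [{xrefs}]')
        if term.comment:
            lines.append(f"comment: {term.comment}")
        for text, scope in sorted(term.synonyms):
            lines.append(f'synonym: "{_escape(text)}" {scope} []')
        for parent in sorted(term.told_parents):
            lines.append(f"is_a: {parent}")
        if term.logical_def is not None:
            genus = [p for p in term.logical_def.parts if isinstance(p, Named)]
            diffs = [p for p in term.logical_def.parts if isinstance(p, Existential)]
            for g in genus:
                lines.append(f"intersection_of: {g.id}")
            for d in sorted(diffs, key=lambda e: (e.prop, e.filler.id)):
                lines.append(f"intersection_of: {d.prop} {d.filler.id}")
        for prop, target in sorted(term.relationships):
            lines.append(f"relationship: {prop} {target}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        if term.created_by:
            lines.append(f"created_by: {term.created_by}")
        if term.creation_date:
            lines.append(f"creation_date: {term.creation_date}")
        lines.extend(term.extra_lines)

    for pid in sorted(ont.properties):
        prop = ont.properties[pid]
        lines.append("")
        lines.append("[Typedef]")
        lines.append(f"id: {prop.id}")
        if prop.label:
            lines.append(f"name: {prop.label}")
        for parent in sorted(prop.parents):
            lines.append(f"is_a: {parent}")
        if prop.transitive:
            lines.append("is_transitive: true")
        lines.extend(prop.extra_lines)

    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Editing operations (copy-on-write)

def apply_new_term(ont: Ontology, term: TermRecord, relation_rewrites=()) -> Ontology:
    """Return a new ontology with *term* added and is_a rewrites applied.

    Each rewrite ``(child, drop_parent, add_parent)`` replaces the
    child's told is_a link to *drop_parent* with one to *add_parent*.
    The input ontology value is not mutated.
    """
    if term.id in ont.terms and not ont.terms[term.id].stub:
        raise DuplicateIdError(f"term id already present: {term.id}")
    out = ont.copy()
    out.terms[term.id] = copy.deepcopy(term)
    for child, drop_parent, add_parent in relation_rewrites:
        for cid in (child, add_parent):
            if cid not in out.terms:
                raise UnknownClassError(f"rewrite references unknown class: {cid}")
        child_term = out.terms[child]
        if drop_parent not in child_term.told_parents:
            raise UnknownClassError(
                f"{child} has no told is_a link to {drop_parent} to rewrite"
            )
        child_term.told_parents.discard(drop_parent)
        child_term.told_parents.add(add_parent)
    return out


def obsolete_term(ont: Ontology, class_id: str, reason: str) -> Ontology:
    """Return a new ontology with *class_id* marked obsolete.

    The term keeps its label; told parents, relationships and the
    logical definition are cleared and the reason recorded in the
    comment field.  No other term is touched.
    """
    if class_id not in ont.terms:
        raise UnknownClassError(f"unknown term: {class_id}")
    if ont.terms[class_id].obsolete:
        raise TermforgeError(f"term already obsolete: {class_id}")
    out = ont.copy()
    term = out.terms[class_id]
    term.obsolete = True
    term.told_parents = set()
    term.relationships = set()
    term.logical_def = None
    term.comment = reason
    return out
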