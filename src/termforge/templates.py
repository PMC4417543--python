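"""Declarative class-generation templates.

A template is an ontology design pattern made executable: a logical
pattern (an equivalence-axiom skeleton with ``?X``-style variables), a
label and textual-definition pattern, and optional synonym rules.
Filling the input fields of a template with ontology classes yields a
fully grounded candidate class — logical definition, label, textual
definition, synonyms — ready for reasoner placement and review.

Pattern grammar (one line per template)::

    pattern   := conjunct (" and " conjunct)*
    conjunct  := genus | relation | "[" relation "]"      (optional)
    genus     := CURIE | 'label' | ?VAR
    relation  := 'relation label' "some" (CURIE | ?VAR | 'label')

Bracketed conjuncts are optional and tied to the (optional) field of
their variable.  Relation labels are resolved through the
label-to-property map shipped in the same configuration file.

Text patterns use ``[X]`` for the bound class label, ``[X.id]`` for
its CURIE, and ``[[ ... ]]`` for a segment that is dropped entirely
when the optional field it mentions is unbound.

Templates are plain data (YAML), not code: every pattern in the
shipped catalogue is expressible in this grammar, and nothing
user-supplied is ever executed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import BindingError, PatternError, TemplateConfigError
from .expressions import (
    Expr,
    LabelRef,
    Named,
    Variable,
    canonical,
    conjunction_of,
    is_grounded,
    iter_variables,
    substitute,
)
from .obo import SYNONYM_SCOPES, Ontology
from .reasoner import subclass_closure

REFERENCE_FIELD = "ref"
_XREF_RE = re.compile(r"^\S+:\S+$")


# ---------------------------------------------------------------------------
# Pattern model

@dataclass(frozen=True)
class PatternConjunct:
    expr: Expr
    optional_for: str | None = None  # variable name gating an optional conjunct


@dataclass(frozen=True)
class Pattern:
    conjuncts: tuple

    def variables(self) -> set[str]:
        out: set[str] = set()
        for c in self.conjuncts:
            out |= set(iter_variables(c.expr))
        return out


_TOKEN_RE = re.compile(r"\?[A-Za-z_]\w*|'[^']*'|\[|\]|\S+")


def parse_pattern(text: str, relation_map: dict) -> Pattern:
    """Parse a pattern string into conjuncts with variable leaves."""
    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise PatternError(f"unexpected end of pattern: {text!r}")
        pos += 1
        return tok

    def parse_primary(tok: str) -> Expr:
        if tok.startswith("?"):
            return Variable(tok[1:])
        if tok.startswith("'"):
            return LabelRef(tok[1:-1])
        if ":" in tok:
            return Named(tok)
        raise PatternError(f"cannot parse {tok!r} in pattern {text!r}")

    def parse_conjunct() -> Expr:
        tok = take()
        if tok.startswith("'") and peek() == "some":
            take()  # some
            filler = parse_primary(take())
            label = tok[1:-1]
            prop = relation_map.get(label)
            if prop is None:
                raise PatternError(
                    f"unknown relation label {label!r} in pattern {text!r}"
                )
            from .expressions import Existential

            return Existential(prop, filler)
        return parse_primary(tok)

    conjuncts: list[PatternConjunct] = []
    first = True
    while peek() is not None:
        optional = False
        if not first:
            tok = take()
            if tok == "[":
                optional = True
                if peek() == "and":
                    take()
            elif tok != "and":
                raise PatternError(
                    f"expected 'and' between conjuncts, got {tok!r} in {text!r}"
                )
        elif peek() == "[":
            take()
            optional = True
            if peek() == "and":
                take()
        expr = parse_conjunct()
        optional_for = None
        if optional:
            if take() != "]":
                raise PatternError(f"unclosed optional conjunct in {text!r}")
            vars_in = set(iter_variables(expr))
            if len(vars_in) != 1:
                raise PatternError(
                    "an optional conjunct must mention exactly one variable: "
                    f"{text!r}"
                )
            optional_for = vars_in.pop()
        conjuncts.append(PatternConjunct(expr, optional_for))
        first = False
    if not conjuncts:
        raise PatternError("empty pattern")
    return Pattern(tuple(conjuncts))


# ---------------------------------------------------------------------------
# Template model

@dataclass(frozen=True)
class FieldSpec:
    """One typed input field of a template."""

    name: str
    kind: str = "class"  # class | text | xref_list
    required: bool = True
    subset_names: tuple = ()
    subset_roots: tuple = ()  # resolved root class ids

    def __post_init__(self):
        if self.kind not in ("class", "text", "xref_list"):
            raise TemplateConfigError(f"unknown field kind: {self.kind}")
        if self.kind == "class" and not self.subset_roots:
            raise TemplateConfigError(
                f"class field {self.name!r} needs at least one subset root"
            )


@dataclass(frozen=True)
class SynonymRule:
    source_field: str
    scope: str = "EXACT"
    pattern: str = ""


@dataclass(frozen=True)
class TemplateSpec:
    """A complete design pattern: typed fields + logical and textual builders."""

    name: str
    fields: tuple
    pattern: Pattern
    name_pattern: str
    def_pattern: str
    synonym_rules: tuple = ()
    obo_namespace: str = ""
    description: str = ""

    def field_map(self) -> dict:
        return {f.name: f for f in self.fields}

    def class_fields(self) -> tuple:
        return tuple(f for f in self.fields if f.kind == "class")


@dataclass(frozen=True)
class Binding:
    """Values for a template's variables plus the literature reference(s)."""

    values: dict
    references: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "references", tuple(self.references))


@dataclass(frozen=True)
class CandidateTerm:
    """A fully generated candidate class, ready for placement and review."""

    label: str
    definition: str
    def_xrefs: tuple = ()
    synonyms: tuple = ()
    logical_def: Expr | None = None
    namespace: str = ""
    created_by: str = ""
    creation_date: str = ""
    told_parents: tuple = ()  # used by free-form candidates only
    relationships: tuple = ()

    def __post_init__(self):
        if not self.label:
            raise TemplateConfigError("candidate label must be non-empty")
        object.__setattr__(self, "synonyms", tuple(sorted(self.synonyms)))
        object.__setattr__(self, "def_xrefs", tuple(self.def_xrefs))
        object.__setattr__(self, "told_parents", tuple(sorted(self.told_parents)))
        object.__setattr__(self, "relationships",
                           tuple(sorted(self.relationships)))


@dataclass(frozen=True)
class CheckFailure:
    """A single validation failure (data, not an exception)."""

    field: str
    message: str

    def __str__(self):
        return f"{self.field}: {self.message}"


@dataclass
class TemplateConfig:
    templates: list = field(default_factory=list)
    relations: dict = field(default_factory=dict)
    subsets: dict = field(default_factory=dict)  # name -> list of roots

    def by_name(self, name: str) -> TemplateSpec:
        for t in self.templates:
            if t.name == name:
                return t
        raise TemplateConfigError(f"no such template: {name}")


# ---------------------------------------------------------------------------
# Loading

def load_template_config(source) -> TemplateConfig:
    """Load a template configuration from a path, YAML text, or dict."""
    if isinstance(source, dict):
        data = source
    elif isinstance(source, Path):
        data = yaml.safe_load(source.read_text())
    elif (isinstance(source, str) and source and "\n" not in source
          and Path(source).is_file()):
        data = yaml.safe_load(Path(source).read_text())
    else:
        data = yaml.safe_load(source)
    if data is None:
        return TemplateConfig()
    relations = dict(data.get("relations", {}))
    subsets = {k: list(v) for k, v in (data.get("subsets", {}) or {}).items()}

    templates: list[TemplateSpec] = []
    seen: set[str] = set()
    for entry in data.get("templates", []) or []:
        name = entry.get("name")
        if not name:
            raise TemplateConfigError("template without a name")
        if name in seen:
            raise TemplateConfigError(f"duplicate template name: {name}")
        seen.add(name)

        fields = []
        for f in entry.get("fields", []) or []:
            subset_names = tuple(f.get("subsets", ()))
            roots: list[str] = []
            for sname in subset_names:
                if sname not in subsets:
                    raise TemplateConfigError(
                        f"template {name}: unknown subset {sname!r}"
                    )
                roots.extend(subsets[sname])
            roots.extend(f.get("roots", ()))
            fields.append(
                FieldSpec(
                    name=f["name"],
                    kind=f.get("kind", "class"),
                    required=f.get("required", True),
                    subset_names=subset_names,
                    subset_roots=tuple(roots),
                )
            )
        field_names = {f.name for f in fields}
        if len(field_names) != len(fields):
            raise TemplateConfigError(f"template {name}: duplicate field names")

        pattern = parse_pattern(entry["pattern"], relations)
        undeclared = pattern.variables() - field_names
        if undeclared:
            raise TemplateConfigError(
                f"template {name}: pattern variable(s) {sorted(undeclared)} "
                "not declared as fields"
            )
        fmap = {f.name: f for f in fields}
        for conj in pattern.conjuncts:
            if conj.optional_for and fmap[conj.optional_for].required:
                raise TemplateConfigError(
                    f"template {name}: optional conjunct bound to required "
                    f"field {conj.optional_for}"
                )
        n_class = sum(1 for f in fields if f.kind == "class")
        if not 1 <= n_class <= 3:
            raise TemplateConfigError(
                f"template {name}: needs between 1 and 3 class fields, "
                f"got {n_class}"
            )
        rules = tuple(
            SynonymRule(
                source_field=r["field"],
                scope=r.get("scope", "EXACT"),
                pattern=r["pattern"],
            )
            for r in entry.get("synonym_rules", []) or []
        )
        for r in rules:
            if r.scope not in SYNONYM_SCOPES:
                raise TemplateConfigError(
                    f"template {name}: bad synonym scope {r.scope}"
                )
            if r.source_field not in field_names:
                raise TemplateConfigError(
                    f"template {name}: synonym rule references unknown field "
                    f"{r.source_field}"
                )
        templates.append(
            TemplateSpec(
                name=name,
                fields=tuple(fields),
                pattern=pattern,
                name_pattern=entry.get("name_pattern", ""),
                def_pattern=entry.get("def_pattern", ""),
                synonym_rules=rules,
                obo_namespace=entry.get("namespace", ""),
                description=entry.get("description", ""),
            )
        )
    return TemplateConfig(templates=templates, relations=relations,
                          subsets=subsets)


def load_templates(source) -> list:
    """Convenience wrapper returning just the template list."""
    return load_template_config(source).templates


def builtin_template_config() -> TemplateConfig:
    """The shipped template catalogue (GO-style cross-product patterns)."""
    text = resources.files("termforge.data").joinpath("go_templates.yaml").read_text()
    return load_template_config(text)


# ---------------------------------------------------------------------------
# Validation and instantiation

def validate_binding(
    template: TemplateSpec,
    binding: Binding,
    ontology: Ontology,
    closures: dict | None = None,
) -> list:
    """Check a binding against the template; returns failures (no raise).

    *closures* may carry precomputed ``root-tuple -> subclass closure``
    sets to avoid re-saturating the ontology for every call.
    """
    failures: list[CheckFailure] = []
    fmap = template.field_map()

    for fname in binding.values:
        if fname not in fmap:
            failures.append(CheckFailure(fname, "not a field of this template"))

    for f in template.fields:
        value = binding.values.get(f.name)
        if value in (None, ""):
            if f.required:
                failures.append(CheckFailure(f.name, "required field is missing"))
            continue
        if f.kind != "class":
            continue
        term = ontology.terms.get(value)
        if term is None:
            failures.append(CheckFailure(f.name, f"unknown class {value}"))
            continue
        if term.obsolete:
            failures.append(CheckFailure(f.name, f"{value} is obsolete"))
            continue
        key = tuple(f.subset_roots)
        if closures is not None and key in closures:
            closure = closures[key]
        else:
            closure = subclass_closure(ontology, f.subset_roots)
            if closures is not None:
                closures[key] = closure
        if value not in closure:
            failures.append(
                CheckFailure(
                    f.name,
                    f"{value} is outside the allowed subset "
                    f"(roots: {', '.join(f.subset_roots)})",
                )
            )

    if not binding.references:
        failures.append(
            CheckFailure(REFERENCE_FIELD, "missing literature reference")
        )
    else:
        for ref in binding.references:
            if not _XREF_RE.match(ref):
                failures.append(
                    CheckFailure(
                        REFERENCE_FIELD,
                        f"malformed reference {ref!r} (expected PREFIX:value)",
                    )
                )
    return failures


_OPTIONAL_SEGMENT_RE = re.compile(r"\[\[((?:[^\[\]]|\[[^\]]*\])*)\]\]")
_PLACEHOLDER_RE = re.compile(r"\[([A-Za-z_]\w*)(\.id)?\]")


def _render(pattern_text: str, labels: dict, ids: dict, bound: set) -> str:
    def segment(m: re.Match) -> str:
        inner = m.group(1)
        mentioned = {p.group(1) for p in _PLACEHOLDER_RE.finditer(inner)}
        if mentioned - bound:
            return ""
        return inner

    text = _OPTIONAL_SEGMENT_RE.sub(segment, pattern_text)

    def fill(m: re.Match) -> str:
        name, want_id = m.group(1), m.group(2)
        if name not in bound:
            raise BindingError(
                [CheckFailure(name, "placeholder for unbound field")]
            )
        return ids[name] if want_id else labels[name]

    return _PLACEHOLDER_RE.sub(fill, text)


def instantiate(
    template: TemplateSpec,
    binding: Binding,
    ontology: Ontology,
    created_by: str = "",
    creation_date: str = "",
    closures: dict | None = None,
) -> CandidateTerm:
    """Ground the template with a validated binding into a candidate term."""
    failures = validate_binding(template, binding, ontology, closures)
    if failures:
        raise BindingError(failures)

    fmap = template.field_map()
    bound = {n for n, v in binding.values.items() if v not in (None, "")}
    labels: dict[str, str] = {}
    ids: dict[str, str] = {}
    substitution: dict[str, Expr] = {}
    for name in bound:
        value = binding.values[name]
        if fmap[name].kind == "class":
            labels[name] = ontology.label_of(value)
            ids[name] = value
            substitution[name] = Named(value)
        else:
            labels[name] = str(value)
            ids[name] = str(value)

    parts: list[Expr] = []
    for conj in template.pattern.conjuncts:
        if conj.optional_for and conj.optional_for not in bound:
            continue
        expr = substitute(conj.expr, substitution)
        expr = _resolve_labels(expr, ontology)
        parts.append(expr)
    logical_def = conjunction_of(*parts)
    if not is_grounded(logical_def):
        raise BindingError(
            [CheckFailure("pattern", "logical definition is not fully grounded")]
        )

    label = _render(template.name_pattern, labels, ids, bound)
    definition = _render(template.def_pattern, labels, ids, bound)

    synonyms: list[tuple[str, str]] = []
    for rule in template.synonym_rules:
        if rule.source_field not in bound:
            continue
        value = binding.values[rule.source_field]
        source_term = ontology.terms.get(value)
        if source_term is None:
            continue
        for syn_text, syn_scope in source_term.synonyms:
            scope = rule.scope if syn_scope == "EXACT" else "RELATED"
            text = rule.pattern.replace(f"[{rule.source_field}]", syn_text)
            synonyms.append((text, scope))

    return CandidateTerm(
        label=label,
        definition=definition,
        def_xrefs=tuple(binding.references),
        synonyms=tuple(synonyms),
        logical_def=logical_def,
        namespace=template.obo_namespace,
        created_by=created_by,
        creation_date=creation_date,
    )


def _resolve_labels(expr: Expr, ontology: Ontology) -> Expr:
    """Replace LabelRef leaves by the named class carrying that label."""
    mapping: dict[str, Expr] = {}
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, LabelRef):
            term = ontology.term_by_label(e.label)
            if term is None:
                raise BindingError(
                    [CheckFailure("pattern", f"no class labelled {e.label!r}")]
                )
            mapping[canonical(e)] = Named(term.id)
        elif hasattr(e, "parts"):
            stack.extend(e.parts)
        elif hasattr(e, "filler"):
            stack.append(e.filler)
    return substitute(expr, mapping) if mapping else expr
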