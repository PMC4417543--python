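"""Exception hierarchy shared across the package.

All domain-level failures derive from :class:`TermforgeError` so callers
(and the command-line front end) can distinguish them from programming
errors.
"""

from __future__ import annotations


class TermforgeError(Exception):
    """Base class for all domain errors raised by termforge."""


class OboParseError(TermforgeError):
    """Syntactic or referential error while reading an OBO document."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class OboLoadWarning(UserWarning):
    """Non-fatal issue noticed while loading an ontology (e.g. an is_a
    link pointing at an obsolete term)."""


class DuplicateIdError(TermforgeError):
    """A class identifier is already present in the ontology."""


class UnknownClassError(TermforgeError):
    """A class identifier does not resolve in the loaded ontology."""


class UnknownPropertyError(TermforgeError):
    """A relation identifier does not resolve in the loaded ontology."""


class IncoherentOntologyError(TermforgeError):
    """Classification was requested on an ontology with unsatisfiable
    named classes."""

    def __init__(self, unsatisfiable):
        self.unsatisfiable = frozenset(unsatisfiable)
        names = ", ".join(sorted(self.unsatisfiable))
        super().__init__(f"ontology is incoherent; unsatisfiable classes: {names}")


class PatternError(TermforgeError):
    """A template pattern string violates the pattern grammar."""


class TemplateConfigError(TermforgeError):
    """A template configuration file is malformed."""


class BindingError(TermforgeError):
    """A binding failed validation; carries the individual failures."""

    def __init__(self, failures):
        self.failures = list(failures)
        super().__init__("; ".join(str(f) for f in self.failures))


class UnauthorizedError(TermforgeError):
    """Requester is not on the relevant allow-list."""


class DuplicateClassError(TermforgeError):
    """The candidate class is logically equivalent to an existing class."""

    def __init__(self, existing_ids):
        self.existing_ids = tuple(sorted(existing_ids))
        super().__init__(
            "candidate is equivalent to existing class(es): "
            + ", ".join(self.existing_ids)
        )


class UnsatisfiableCandidateError(TermforgeError):
    """The candidate class expression is unsatisfiable."""


class IdRangeExhaustedError(TermforgeError):
    """No unallocated identifier remains in the configured range."""


class QueueStateError(TermforgeError):
    """Illegal request lifecycle transition or unknown request."""


class SimilarLabelError(TermforgeError):
    """A free-form request was blocked by label-similarity warnings."""

    def __init__(self, warnings_):
        self.warnings = list(warnings_)
        detail = "; ".join(
            f"{w.existing_id} {w.existing_text!r} ({w.kind}, d={w.distance})"
            for w in self.warnings
        )
        super().__init__(f"similar existing labels/synonyms: {detail}")
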