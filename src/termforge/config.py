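"""Application configuration: one YAML file wires ontology paths,
template catalogue, identifier policy, allow-lists and queue paths.

Example::

    ontologies: [go-mini.obo]
    external_prefixes: [CHEBI, PO, CL, UBERON, PATO, TEST]
    templates: builtin          # or a path to a template YAML
    subsets: {}                 # optional; defaults to the template config's
    id_policy:
      prefix: GO
      width: 7
      range_start: 2000001
      range_end: 2001000
      state: id-state.json
    allow_templated: [curator@example.org]
    allow_freeform: [senior@example.org]
    queue: queue.jsonl
    changelog: changelog.tsv

Missing allow-lists mean "anyone"; all paths are resolved relative to
the configuration file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import TermforgeError
from .obo import Ontology, parse_obo
from .pipeline import IdPolicy, RequestQueue
from .templates import TemplateConfig, builtin_template_config, load_template_config


@dataclass
class AppConfig:
    base_dir: Path
    ontology_paths: tuple
    external_prefixes: tuple = ()
    templates_source: str = "builtin"
    subsets_override: dict = field(default_factory=dict)
    id_policy_spec: dict = field(default_factory=dict)
    allow_templated: tuple | None = None
    allow_freeform: tuple | None = None
    queue_path: Path | None = None
    changelog_path: Path | None = None

    _ontology: Ontology | None = None
    _template_config: TemplateConfig | None = None

    @classmethod
    def load(cls, path) -> "AppConfig":
        path = Path(path)
        if not path.exists():
            raise TermforgeError(f"no such config file: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def resolve(p):
            return (base / p) if p else None

        paths = tuple(resolve(p) for p in data.get("ontologies", []) or [])
        seen = set()
        mutable = [
            resolve(data.get("queue")),
            resolve(data.get("changelog")),
            resolve((data.get("id_policy") or {}).get("state")),
        ]
        for p in mutable:
            if p is not None:
                if p in seen:
                    raise TermforgeError(f"config paths must be distinct: {p}")
                seen.add(p)
        return cls(
            base_dir=base,
            ontology_paths=paths,
            external_prefixes=tuple(data.get("external_prefixes", []) or []),
            templates_source=data.get("templates", "builtin"),
            subsets_override=dict(data.get("subsets", {}) or {}),
            id_policy_spec=dict(data.get("id_policy", {}) or {}),
            allow_templated=(
                tuple(data["allow_templated"])
                if data.get("allow_templated") is not None else None
            ),
            allow_freeform=(
                tuple(data["allow_freeform"])
                if data.get("allow_freeform") is not None else None
            ),
            queue_path=resolve(data.get("queue")),
            changelog_path=resolve(data.get("changelog")),
        )

    # -- loaded artefacts ---------------------------------------------
    def ontology(self) -> Ontology:
        """The merged multi-ontology workspace."""
        if self._ontology is None:
            if not self.ontology_paths:
                raise TermforgeError("no ontologies configured")
            merged: Ontology | None = None
            for p in self.ontology_paths:
                ont = parse_obo(Path(p).read_text(), self.external_prefixes)
                if merged is None:
                    merged = ont
                else:
                    merged.merge(ont)
            self._ontology = merged
        return self._ontology

    def template_config(self) -> TemplateConfig:
        if self._template_config is None:
            if self.templates_source in ("builtin", "", None):
                self._template_config = builtin_template_config()
            else:
                self._template_config = load_template_config(
                    self.base_dir / self.templates_source
                )
        return self._template_config

    def subsets(self) -> dict:
        return self.subsets_override or self.template_config().subsets

    def policy(self) -> IdPolicy:
        spec = self.id_policy_spec
        if not spec:
            raise TermforgeError("no id_policy configured")
        state = spec.get("state")
        return IdPolicy(
            prefix=spec["prefix"],
            width=int(spec.get("width", 7)),
            range_start=int(spec["range_start"]),
            range_end=int(spec["range_end"]),
            state_path=(self.base_dir / state) if state else None,
        )

    def queue(self) -> RequestQueue:
        if self.queue_path is None:
            raise TermforgeError("no queue path configured")
        return RequestQueue(self.queue_path)

    def primary_ontology_path(self) -> Path:
        if not self.ontology_paths:
            raise TermforgeError("no ontologies configured")
        return Path(self.ontology_paths[0])
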