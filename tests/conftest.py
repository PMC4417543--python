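from __future__ import annotations

import pytest

from termforge.fixtures import camptothecin_fixture, mini_go_chebi
from termforge.obo import write_obo
from termforge.pipeline import IdPolicy, RequestQueue
from termforge.templates import builtin_template_config


@pytest.fixture()
def fig_ont():
    """The camptothecin-catabolism worked-example ontology."""
    return camptothecin_fixture()


@pytest.fixture()
def mini():
    """(ontology, subsets) for the mini GO/ChEBI workspace."""
    return mini_go_chebi()


@pytest.fixture()
def mini_ont(mini):
    return mini[0]


@pytest.fixture(scope="session")
def catalogue():
    """The shipped template catalogue (read-only)."""
    return builtin_template_config()


@pytest.fixture()
def workspace(tmp_path, mini_ont):
    """A working directory with ontology file, id policy and queue."""
    obo_path = tmp_path / "go.obo"
    obo_path.write_text(write_obo(mini_ont))
    policy = IdPolicy("GO", 7, 2000001, 2003000,
                      state_path=tmp_path / "ids.json")
    queue = RequestQueue(tmp_path / "queue.jsonl")
    return {
        "dir": tmp_path,
        "obo": obo_path,
        "policy": policy,
        "queue": queue,
        "changelog": tmp_path / "changelog.tsv",
    }
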