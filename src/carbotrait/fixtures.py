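"""Packaged reference fixtures.

Ships the 41-strain x 18-sugar *Oenococcus oeni* growth-phenotype panel
(branches A/B/C of the species dendrogram), per-sugar gene functionality-state
matrices restricted to the strains and states documented for that sugar, and
the per-sugar pathway rules. Gene-state cells not individually documented
default to INTACT (or ABSENT for strain-specific isoforms) and are listed in a
sidecar `*_stated.json` file so the assumptions stay auditable; the phenotype
panel likewise ships a `table1_assumed.json` sidecar for the cells that are
fixed by the row/column totals rather than by a named statement.
"""
from __future__ import annotations

import hashlib
import json
from importlib import resources

from .datamodel import GeneStateMatrix, PathwayModel, PhenotypeMatrix
from .io import read_gene_state_matrix, read_pathway_model, read_phenotype_matrix

__all__ = ["load_fixture", "fixture_names", "normalize_strain_id",
           "fixture_checksums", "stated_cells"]

_STATE_FIXTURES = ("arabinose", "ribose", "mannose", "fructose", "trehalose",
                   "melibiose", "maltose")
_RULE_FIXTURES = _STATE_FIXTURES + ("glucose",)


def _data_dir():
    return resources.files("carbotrait") / "data"


def fixture_names() -> list[str]:
    names = ["table1"]
    names += [f"{s}_states" for s in _STATE_FIXTURES]
    names += [f"rules/{s}" for s in _RULE_FIXTURES]
    return names


def _branches() -> dict[str, str]:
    out = {}
    text = (_data_dir() / "table1_strains.tsv").read_text(encoding="utf-8")
    for line in text.splitlines()[1:]:
        strain, branch, *_ = line.split("\t")
        out[strain] = branch
    return out


def load_fixture(name: str) -> PhenotypeMatrix | GeneStateMatrix | PathwayModel:
    """Load a packaged fixture by registry name.

    Names: ``"table1"`` (phenotype panel with branch labels),
    ``"<sugar>_states"`` for the gene-state matrices, and ``"rules/<sugar>"``
    for the pathway models (see :func:`fixture_names`).
    """
    data = _data_dir()
    if name == "table1":
        with resources.as_file(data / "table1.tsv") as p:
            return read_phenotype_matrix(p, branch_of=_branches())
    if name.endswith("_states") and name[:-7] in _STATE_FIXTURES:
        with resources.as_file(data / f"{name}.tsv") as p:
            return read_gene_state_matrix(p)
    if name.startswith("rules/") and name[6:] in _RULE_FIXTURES:
        with resources.as_file(data / "rules" / f"{name[6:]}.json") as p:
            return read_pathway_model(p)
    raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}")


def stated_cells(name: str) -> dict:
    """Sidecar metadata: which cells of a fixture are documented vs assumed."""
    data = _data_dir()
    if name == "table1":
        path = data / "table1_assumed.json"
    elif name.endswith("_states") and name[:-7] in _STATE_FIXTURES:
        path = data / f"{name}_stated.json"
    else:
        raise KeyError(f"no sidecar for fixture {name!r}")
    return json.loads(path.read_text(encoding="utf-8"))


def normalize_strain_id(strain: str) -> str:
    """Map alternate strain spellings to the panel's canonical form."""
    aliases = json.loads(
        (_data_dir() / "strain_aliases.json").read_text(encoding="utf-8"))
    s = strain.strip()
    return aliases.get(s, s)


def fixture_checksums() -> dict[str, str]:
    """sha256 of every packaged data file, for run provenance logging."""
    out = {}
    data = _data_dir()
    for entry in sorted(data.iterdir(), key=lambda e: e.name):
        if entry.is_file():
            out[entry.name] = hashlib.sha256(entry.read_bytes()).hexdigest()
        elif entry.name == "rules":
            for rule in sorted(entry.iterdir(), key=lambda e: e.name):
                out[f"rules/{rule.name}"] = hashlib.sha256(
                    rule.read_bytes()).hexdigest()
    return out
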