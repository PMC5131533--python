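"""Readers and writers for the package's exchange formats.

TSV (UTF-8, header row of sugar/gene ids, first column of strain ids) for both
matrices; Newick for trees; JSON for pathway models. Phenotype TSVs use "1"
for growth and "0" or an empty cell for no growth — printed survey tables
typically mark only the positives.
"""
from __future__ import annotations

import csv
import json
from os import PathLike
from typing import Union

import dendropy
import pandas as pd

from .datamodel import (GeneState, GeneStateMatrix, PathwayModel,
                        PhenotypeMatrix, Phylogeny)

Pathish = Union[str, PathLike]

_LONG_STATES = {"ABSENT": "A", "PSEUDOGENE": "P", "SINGULAR": "S",
                "INTACT": "I"}


def _read_tsv(path: Pathish) -> tuple[list[str], list[str], list[list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or len(rows[0]) < 2:
        raise ValueError(f"{path}: expected a header row with at least one "
                         "id column and one data column")
    header = [h.strip() for h in rows[0][1:]]
    ids, body = [], []
    for r in rows[1:]:
        if not r or (len(r) == 1 and not r[0].strip()):
            continue
        ids.append(r[0].strip())
        cells = [c.strip() for c in r[1:]]
        cells += [""] * (len(header) - len(cells))  # trailing blanks trimmed
        body.append(cells[:len(header)])
    return header, ids, body


def read_phenotype_matrix(path: Pathish,
                          branch_of: dict[str, str] | None = None
                          ) -> PhenotypeMatrix:
    """Read a strain x sugar growth matrix.

    Cells must be "1", "0" or blank; blank cells are parsed as NEGATIVE
    (printed tables mark only the 1s).
    """
    sugars, strains, body = _read_tsv(path)
    data = []
    for i, row in enumerate(body):
        out = []
        for j, cell in enumerate(row):
            if cell in ("", "0"):
                out.append(0)
            elif cell == "1":
                out.append(1)
            else:
                raise ValueError(
                    f"{path}: cell outside {{0,1,blank}} at row "
                    f"{strains[i]!r}, column {sugars[j]!r}: {cell!r}")
        data.append(out)
    values = pd.DataFrame(data, index=strains, columns=sugars, dtype="int8")
    return PhenotypeMatrix(values, branch_of=branch_of)


def write_phenotype_matrix(matrix: PhenotypeMatrix, path: Pathish,
                           blank_negatives: bool = False) -> None:
    df = matrix.values
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["strain", *df.columns])
        for strain, row in df.iterrows():
            cells = [("1" if v else ("" if blank_negatives else "0"))
                     for v in row]
            w.writerow([strain, *cells])


def read_gene_state_matrix(path: Pathish) -> GeneStateMatrix:
    """Read a strain x gene functionality-state matrix.

    Cells are single-letter codes A/P/S/I or the long names
    ABSENT/PSEUDOGENE/SINGULAR/INTACT (case-insensitive).
    """
    genes, strains, body = _read_tsv(path)
    data = []
    for i, row in enumerate(body):
        out = []
        for j, cell in enumerate(row):
            token = _LONG_STATES.get(cell.upper(), cell.upper())
            try:
                out.append(GeneState(token).value)
            except ValueError:
                raise ValueError(
                    f"{path}: unknown state token {cell!r} at row "
                    f"{strains[i]!r}, column {genes[j]!r}") from None
        data.append(out)
    states = pd.DataFrame(data, index=strains, columns=genes)
    return GeneStateMatrix(states)


def write_gene_state_matrix(matrix: GeneStateMatrix, path: Pathish) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["strain", *matrix.states.columns])
        for strain, row in matrix.states.iterrows():
            w.writerow([strain, *row.tolist()])


def read_tree(path: Pathish) -> Phylogeny:
    """Read a rooted Newick tree with unique tip labels."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"{path}: Newick parse failure: {exc}") from None
    return Phylogeny(tree)


def parse_tree(newick: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"Newick parse failure: {exc}") from None
    return Phylogeny(tree)


def write_tree(phylogeny: Phylogeny, path: Pathish) -> None:
    phylogeny.tree.write(path=str(path), schema="newick",
                         unquoted_underscores=True)


def read_pathway_model(path: Pathish) -> PathwayModel:
    """Read and structurally validate a pathway-model JSON file.

    Format: ``{"sugar": str, "name": str, "routes": [[[gene, ...], ...], ...]}``
    where the inner lists are isoform groups (OR) and each route is their
    conjunction (AND).
    """
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return PathwayModel.from_dict(d)


def write_pathway_model(model: PathwayModel, path: Pathish) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")
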