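"""Core domain types.

The package works on three tabular objects — a binary growth-phenotype matrix
(strains x sugars), a gene functionality-state matrix (strains x genes, four
states), and a monotone OR-of-AND pathway model — plus a policy mapping
functionality states to a functional/non-functional flag and a thin wrapper
around a dendropy tree.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "Phenotype", "GeneState", "PhenotypeMatrix", "GeneStateMatrix",
    "Phylogeny", "PathwayModel", "FunctionalityPolicy",
]


class Phenotype(enum.Enum):
    """Growth call on a single carbohydrate."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"


class GeneState(enum.Enum):
    """Functionality state of one gene in one strain.

    ABSENT: gene not found; PSEUDOGENE: truncated/disrupted copy;
    SINGULAR: strain-specific variant of uncertain functionality;
    INTACT: full-length copy with no disrupting mutation.
    """

    ABSENT = "A"
    PSEUDOGENE = "P"
    SINGULAR = "S"
    INTACT = "I"

    @classmethod
    def parse(cls, token: str) -> "GeneState":
        t = token.strip()
        try:
            return cls(t.upper()) if len(t) == 1 else cls[t.upper()]
        except (ValueError, KeyError):
            raise ValueError(f"unknown gene state token {token!r}") from None


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class PhenotypeMatrix:
    """Binary strain x sugar growth matrix (1 = growth, 0 = no growth).

    ``values`` is a pandas DataFrame of int8 in {0, 1} with strain ids as the
    index and sugar ids as the columns. ``branch_of`` optionally assigns every
    strain to a lineage group label (e.g. "A"/"B"/"C").
    """

    values: pd.DataFrame
    branch_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "strain")
        _check_unique(list(self.values.columns), "sugar")
        bad = ~self.values.isin([0, 1])
        if bad.to_numpy().any():
            r, c = next(zip(*bad.to_numpy().nonzero()))
            raise ValueError(
                f"phenotype entry outside {{0,1}} at strain "
                f"{self.values.index[r]!r}, sugar {self.values.columns[c]!r}")
        self.values = self.values.astype("int8")
        if self.branch_of is not None:
            missing = set(self.values.index) - set(self.branch_of)
            if missing:
                raise ValueError(
                    f"branch_of does not cover strains: {sorted(missing)}")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sugar_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_strains(self) -> int:
        return self.values.shape[0]

    def phenotype(self, strain: str, sugar: str) -> Phenotype:
        v = self.values.at[strain, sugar]
        return Phenotype.POSITIVE if v == 1 else Phenotype.NEGATIVE

    def column(self, sugar: str) -> pd.Series:
        if sugar not in self.values.columns:
            raise KeyError(f"unknown sugar {sugar!r}")
        return self.values[sugar]

    def subset(self, strains: Iterable[str]) -> "PhenotypeMatrix":
        strains = list(strains)
        branch = ({s: self.branch_of[s] for s in strains}
                  if self.branch_of else None)
        return PhenotypeMatrix(self.values.loc[strains].copy(), branch)


@dataclass
class GeneStateMatrix:
    """Strain x gene matrix of :class:`GeneState` codes.

    ``states`` holds single-character codes ("A", "P", "S", "I") in a pandas
    DataFrame with strain ids as index and gene ids as columns.
    """

    states: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.states.index), "strain")
        _check_unique(list(self.states.columns), "gene")
        valid = {s.value for s in GeneState}
        bad = ~self.states.isin(valid)
        if bad.to_numpy().any():
            r, c = next(zip(*bad.to_numpy().nonzero()))
            raise ValueError(
                f"unknown gene state {self.states.iat[r, c]!r} at strain "
                f"{self.states.index[r]!r}, gene {self.states.columns[c]!r}")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.states.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.states.columns)

    def state(self, strain: str, gene: str) -> GeneState:
        return GeneState(self.states.at[strain, gene])

    def functional(self, policy: "FunctionalityPolicy") -> pd.DataFrame:
        """Boolean strain x gene matrix under the given policy."""
        out = {}
        for g in self.states.columns:
            col = self.states[g]
            out[g] = col.map(lambda c, g=g: policy.is_functional(
                GeneState(c), g))
        return pd.DataFrame(out, index=self.states.index)

    def subset(self, strains: Iterable[str]) -> "GeneStateMatrix":
        return GeneStateMatrix(self.states.loc[list(strains)].copy())


@dataclass
class Phylogeny:
    """Rooted strain tree; tips are strain ids."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        _check_unique(labels, "tip")
        if len(labels) < 2:
            raise ValueError("phylogeny needs at least 2 tips")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def check_matches(self, strain_ids: Iterable[str]) -> None:
        tips, strains = set(self.tip_labels), set(strain_ids)
        if tips != strains:
            raise ValueError(
                "tree tips do not match strain set; "
                f"tree-only={sorted(tips - strains)}, "
                f"matrix-only={sorted(strains - tips)}")

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def _canonical_routes(
    routes: Iterable[Iterable[Iterable[str]]],
) -> tuple[tuple[frozenset[str], ...], ...]:
    canon = []
    for route in routes:
        groups = tuple(sorted((frozenset(g) for g in route),
                              key=lambda g: sorted(g)))
        for g in groups:
            if not g:
                raise ValueError("isoform group must be non-empty")
        canon.append(groups)
    return tuple(sorted(canon, key=lambda r: [sorted(g) for g in r]))


@dataclass(frozen=True)
class PathwayModel:
    """Monotone OR-of-AND rule predicting growth on one sugar.

    The strain is predicted POSITIVE when at least one route is satisfied; a
    route is satisfied when every one of its isoform groups contains at least
    one functional gene. An empty route list predicts NEGATIVE for every
    strain; a route with no groups is always satisfied (predicts POSITIVE
    for every strain).
    """

    sugar: str
    routes: tuple[tuple[frozenset[str], ...], ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "routes", _canonical_routes(self.routes))

    def genes(self) -> set[str]:
        return {g for route in self.routes for grp in route for g in grp}

    def n_literals(self) -> int:
        return sum(len(grp) for route in self.routes for grp in route)

    # --- JSON round trip (format: {"sugar": .., "routes": [[[gene,..],..],..]})
    def to_dict(self) -> dict:
        return {"sugar": self.sugar, "name": self.name,
                "routes": [[sorted(g) for g in route] for route in self.routes]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PathwayModel":
        if not isinstance(d, Mapping):
            raise ValueError("pathway model must be a JSON object")
        if "sugar" not in d or not isinstance(d["sugar"], str):
            raise ValueError("pathway model needs a string 'sugar' field")
        routes = d.get("routes")
        if not isinstance(routes, list):
            raise ValueError("pathway model needs a 'routes' list")
        for route in routes:
            if not isinstance(route, list):
                raise ValueError("each route must be a list of isoform groups")
            for grp in route:
                if (not isinstance(grp, list) or not grp
                        or not all(isinstance(g, str) for g in grp)):
                    raise ValueError(
                        "each isoform group must be a non-empty list of "
                        "gene-id strings")
        return cls(sugar=d["sugar"], routes=tuple(
            tuple(frozenset(g) for g in route) for route in routes),
            name=str(d.get("name", "")))


_DEFAULT_FUNCTIONAL = {
    GeneState.INTACT: True,
    GeneState.ABSENT: False,
    GeneState.PSEUDOGENE: False,
    GeneState.SINGULAR: False,
}


@dataclass(frozen=True)
class FunctionalityPolicy:
    """Maps gene states to a functional flag, with per-gene overrides.

    The default treats only INTACT as functional; SINGULAR (strain-specific
    variant) is conservatively non-functional, which matching against real
    data supports for e.g. PTS permease IIC-subunit variants, but individual
    models may override it per gene (some singular variants lie outside the
    catalytic site and are tolerated).
    """

    default: Mapping[GeneState, bool] = field(
        default_factory=lambda: dict(_DEFAULT_FUNCTIONAL))
    overrides: Mapping[str, Mapping[GeneState, bool]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(GeneState) - set(self.default)
        if missing:
            raise ValueError(
                f"policy default map must cover all states, missing {missing}")

    def is_functional(self, state: GeneState, gene: str | None = None) -> bool:
        if gene is not None and gene in self.overrides:
            ov = self.overrides[gene]
            if state in ov:
                return bool(ov[state])
        return bool(self.default[state])

    @classmethod
    def default_policy(cls) -> "FunctionalityPolicy":
        return cls()

    def with_override(self, gene: str, state: GeneState,
                      functional: bool) -> "FunctionalityPolicy":
        ov = {g: dict(m) for g, m in self.overrides.items()}
        ov.setdefault(gene, {})[state] = functional
        return FunctionalityPolicy(dict(self.default), ov)
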