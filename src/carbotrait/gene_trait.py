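"""Gene-trait matching: associating gene functionality with growth phenotypes.

For each (gene, sugar) pair the strains are cross-classified into a 2x2 table
(functional/non-functional x positive/negative) under a functionality policy.
The primary statistic is the two-sided Fisher exact test computed by the
point-probability method in exact rational arithmetic. Because lineages differ
systematically in versatility (branch A strains use fewer sugars than branch
B/C strains), a naive test conflates gene effects with lineage membership; a
within-lineage permutation test is therefore provided as a phylogeny-aware
guard: phenotype labels are shuffled only within lineage groups, so any
association explained purely by branch structure is null under the permuted
distribution.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datamodel import FunctionalityPolicy, GeneStateMatrix, PhenotypeMatrix

__all__ = ["ContingencyTable2x2", "AssociationResult", "build_table",
           "fisher_exact_two_sided", "odds_ratio_statistic",
           "lineage_permutation_p", "screen_all"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (func+pos, func+neg, nonfunc+pos, nonfunc+neg)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def perfect(self) -> bool:
        """Gene functionality separates the phenotypes exactly (either way)."""
        has_func = self.a + self.b > 0
        has_nonf = self.c + self.d > 0
        has_pos = self.a + self.c > 0
        has_neg = self.b + self.d > 0
        if not (has_func and has_nonf and has_pos and has_neg):
            return False
        return (self.b == 0 and self.c == 0) or (self.a == 0 and self.d == 0)

    @property
    def degenerate(self) -> bool:
        """No variation in gene state or in phenotype."""
        return (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0)


@dataclass
class AssociationResult:
    gene_id: str
    sugar_id: str
    table: ContingencyTable2x2
    p_exact: float
    q_fdr: float = float("nan")
    p_perm: float | None = None
    perfect: bool = False
    degenerate: bool = False


def build_table(genes: GeneStateMatrix, phenotypes: PhenotypeMatrix,
                gene: str, sugar: str,
                policy: FunctionalityPolicy | None = None
                ) -> ContingencyTable2x2:
    """Cross-classify the shared strains of the two matrices."""
    if policy is None:
        policy = FunctionalityPolicy.default_policy()
    if gene not in genes.gene_ids:
        raise KeyError(f"gene {gene!r} not in gene-state matrix")
    if sugar not in phenotypes.sugar_ids:
        raise KeyError(f"sugar {sugar!r} not in phenotype matrix")
    shared = [s for s in genes.strain_ids if s in set(phenotypes.strain_ids)]
    if not shared:
        raise ValueError("gene and phenotype matrices share no strains")
    a = b = c = d = 0
    for s in shared:
        func = policy.is_functional(genes.state(s, gene), gene)
        pos = bool(phenotypes.values.at[s, sugar])
        if func and pos:
            a += 1
        elif func:
            b += 1
        elif pos:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def _hypergeom_numerators(table: ContingencyTable2x2
                          ) -> tuple[list[tuple[int, int]], int, int]:
    """Integer numerators C(r1,k)*C(r2,c1-k) over the support, plus observed.

    The common denominator C(n, c1) cancels in all comparisons, so two-sided
    tail selection can be done on exact integers.
    """
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = [(k, math.comb(r1, k) * math.comb(r2, c1 - k))
               for k in range(lo, hi + 1)]
    obs = math.comb(r1, table.a) * math.comb(r2, table.c)
    denom = math.comb(r1 + r2, c1)
    return support, obs, denom


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the point-probability method.

    Sums the hypergeometric probabilities of every table (with the observed
    margins) whose probability is <= that of the observed table. Computed in
    exact integer/rational arithmetic, so ties are handled exactly; the float
    conversion at the end is the only rounding.
    """
    if table.degenerate:
        return 1.0
    support, obs, denom = _hypergeom_numerators(table)
    tail = sum(num for _, num in support if num <= obs)
    return float(Fraction(tail, denom))


def odds_ratio_statistic(table: ContingencyTable2x2) -> float:
    """|log odds ratio| with the Haldane +0.5 correction for zero cells."""
    a, b, c, d = (x + 0.5 for x in (table.a, table.b, table.c, table.d))
    return abs(math.log(a * d / (b * c)))


def _vector_stat(func: np.ndarray, pos: np.ndarray) -> float:
    a = float(np.sum(func & pos)) + 0.5
    b = float(np.sum(func & ~pos)) + 0.5
    c = float(np.sum(~func & pos)) + 0.5
    d = float(np.sum(~func & ~pos)) + 0.5
    return abs(math.log(a * d / (b * c)))


def lineage_permutation_p(genes: GeneStateMatrix, phenotypes: PhenotypeMatrix,
                          gene: str, sugar: str,
                          groups: dict[str, str] | None = None,
                          n_perm: int = 10_000, seed: int | None = None,
                          policy: FunctionalityPolicy | None = None) -> float:
    """Within-lineage permutation p-value for one (gene, sugar) pair.

    Phenotype labels are shuffled independently within each lineage group and
    the |log odds ratio| statistic recomputed; the p-value is
    ``(1 + #{permuted >= observed}) / (1 + n_perm)``. Groups default to the
    matrix's branch labels. Groups with fewer than 2 strains cannot be
    shuffled and are left fixed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable permutation p")
    if policy is None:
        policy = FunctionalityPolicy.default_policy()
    if groups is None:
        if phenotypes.branch_of is None:
            raise ValueError("no groups given and matrix has no branch labels")
        groups = phenotypes.branch_of
    shared = [s for s in genes.strain_ids if s in set(phenotypes.strain_ids)]
    missing = [s for s in shared if s not in groups]
    if missing:
        raise ValueError(f"grouping does not cover strains: {missing}")
    func = np.array([policy.is_functional(genes.state(s, gene), gene)
                     for s in shared])
    pos = phenotypes.values.loc[shared, sugar].to_numpy().astype(bool)
    observed = _vector_stat(func, pos)
    rng = np.random.default_rng(seed)
    group_idx = {}
    for i, s in enumerate(shared):
        group_idx.setdefault(groups[s], []).append(i)
    blocks = [np.array(v) for v in group_idx.values()]
    hits = 0
    perm = pos.copy()
    for _ in range(n_perm):
        for block in blocks:
            if len(block) >= 2:
                perm[block] = pos[block][rng.permutation(len(block))]
        if _vector_stat(func, perm) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def screen_all(genes: GeneStateMatrix, phenotypes: PhenotypeMatrix,
               policy: FunctionalityPolicy | None = None,
               sugars: Sequence[str] | None = None,
               gene_ids: Sequence[str] | None = None,
               groups: dict[str, str] | None = None,
               n_perm: int | None = None, seed: int | None = None,
               alpha: float = 0.05) -> list[AssociationResult]:
    """Genome-wide screen: one association result per (gene, sugar) pair.

    FDR q-values are Benjamini-Hochberg, computed within each sugar. Results
    are sorted by (sugar, q, p, gene). Genes with no state variation are
    reported with p = 1 and a degenerate flag, never dropped. When ``n_perm``
    is given, the within-lineage permutation p is added for every pair.
    """
    if policy is None:
        policy = FunctionalityPolicy.default_policy()
    sugars = list(sugars) if sugars is not None else phenotypes.sugar_ids
    gene_ids = list(gene_ids) if gene_ids is not None else genes.gene_ids
    results: list[AssociationResult] = []
    for sugar in sugars:
        per_sugar = []
        for gene in gene_ids:
            tab = build_table(genes, phenotypes, gene, sugar, policy)
            res = AssociationResult(
                gene_id=gene, sugar_id=sugar, table=tab,
                p_exact=fisher_exact_two_sided(tab),
                perfect=tab.perfect, degenerate=tab.degenerate)
            if n_perm is not None:
                res.p_perm = lineage_permutation_p(
                    genes, phenotypes, gene, sugar, groups=groups,
                    n_perm=n_perm, seed=seed, policy=policy)
            per_sugar.append(res)
        qs = multipletests([r.p_exact for r in per_sugar],
                           alpha=alpha, method="fdr_bh")[1]
        for r, q in zip(per_sugar, qs):
            r.q_fdr = float(q)
        per_sugar.sort(key=lambda r: (r.q_fdr, r.p_exact, r.gene_id))
        results.extend(per_sugar)
    return results


def results_to_rows(results: Iterable[AssociationResult]) -> list[dict]:
    """Flatten results for TSV/JSON output."""
    return [{
        "gene": r.gene_id, "sugar": r.sugar_id,
        "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
        "p_exact": r.p_exact, "p_perm": r.p_perm, "q_fdr": r.q_fdr,
        "perfect": r.perfect, "degenerate": r.degenerate,
    } for r in results]
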