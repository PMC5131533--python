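"""Phenotype calling and substrate-usage statistics.

A growth assay on a single carbohydrate is called POSITIVE when the culture
both changed the pH indicator colour and produced more than 10 mM lactate;
assays under 5 mM lactate are NEGATIVE; anything in between (or a colour/HPLC
disagreement) is INDETERMINATE. OD600 drift alone never flips a call, since
small OD increases occur without any carbohydrate degradation.

The summary statistics mirror how such strain x sugar panels are reported:
per-sugar positive counts and integer percentages, per-strain totals, binned
strain totals, per-lineage-group means, and the sugar preference order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .datamodel import Phenotype, PhenotypeMatrix

__all__ = ["AssayReadout", "UsageSummary", "call_phenotype",
           "substrate_usage", "strain_totals", "bin_strain_totals",
           "group_mean_usage", "preference_order", "summarize"]

LACTATE_POSITIVE_MM = 10.0
LACTATE_NEGATIVE_MM = 5.0


@dataclass(frozen=True)
class AssayReadout:
    """Endpoint readout of one strain x sugar growth assay."""

    strain: str
    sugar: str
    lactate_mM: float
    color_change: bool
    od600_delta: float | None = None

    def __post_init__(self) -> None:
        if self.lactate_mM < 0:
            raise ValueError(
                f"lactate concentration must be >= 0, got {self.lactate_mM}")


def call_phenotype(readout: AssayReadout) -> Phenotype:
    """Call one assay POSITIVE, NEGATIVE or INDETERMINATE.

    POSITIVE requires lactate > 10 mM together with a colour change; lactate
    < 5 mM is NEGATIVE; everything else is INDETERMINATE. ``od600_delta`` is
    deliberately ignored.
    """
    if readout.lactate_mM > LACTATE_POSITIVE_MM and readout.color_change:
        return Phenotype.POSITIVE
    if readout.lactate_mM < LACTATE_NEGATIVE_MM:
        return Phenotype.NEGATIVE
    return Phenotype.INDETERMINATE


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _percent(count: int, n: int) -> int:
    # round-half-up(100*count/n) in exact integer arithmetic
    return (200 * count + n) // (2 * n)


@dataclass
class UsageSummary:
    """All substrate-usage summaries of one phenotype panel."""

    sugar_counts: dict[str, int]
    sugar_percent: dict[str, int]
    strain_totals: dict[str, int]
    preference_order: list[str]
    group_mean: dict[str, dict[str, float]] = field(default_factory=dict)
    bins: dict[str, int] = field(default_factory=dict)


def substrate_usage(matrix: PhenotypeMatrix) -> tuple[dict[str, int],
                                                      dict[str, int]]:
    """Per-sugar positive counts and integer percentages (round half-up)."""
    if matrix.n_strains == 0:
        raise ValueError("empty phenotype matrix")
    counts = matrix.values.sum(axis=0)
    n = matrix.n_strains
    return ({s: int(c) for s, c in counts.items()},
            {s: _percent(int(c), n) for s, c in counts.items()})


def strain_totals(matrix: PhenotypeMatrix) -> dict[str, int]:
    """Number of sugars metabolized by each strain."""
    return {s: int(t) for s, t in matrix.values.sum(axis=1).items()}


def bin_strain_totals(matrix: PhenotypeMatrix,
                      bin_edges: list[int]) -> dict[str, int]:
    """Histogram of per-strain totals over integer bins.

    ``bin_edges`` are strictly increasing cut points; with edges ``[e1, e2]``
    the bins are ``<=e1-1``, ``e1..e2-1`` and ``>=e2``. Counts always sum to
    the number of strains.
    """
    if not bin_edges or any(b <= a for a, b in zip(bin_edges, bin_edges[1:])):
        raise ValueError("bin edges must be non-empty and strictly increasing")
    totals = list(strain_totals(matrix).values())
    edges = [float("-inf"), *bin_edges, float("inf")]
    out: dict[str, int] = {}
    for lo, hi in zip(edges, edges[1:]):
        if lo == float("-inf"):
            label = f"<={int(hi) - 1}"
        elif hi == float("inf"):
            label = f">={int(lo)}"
        else:
            label = f"{int(lo)}-{int(hi) - 1}"
        out[label] = sum(1 for t in totals if lo <= t < hi)
    assert sum(out.values()) == matrix.n_strains
    return out


def group_mean_usage(matrix: PhenotypeMatrix) -> dict[str, dict[str, float]]:
    """Mean number of sugars used per lineage group.

    Returns ``{group: {"raw": float, "rounded": int, "n": int}}``; the rounded
    (half-up) value is the comparison surface, as prose reports rounded means.
    """
    if matrix.branch_of is None:
        raise ValueError("matrix has no branch labels")
    totals = strain_totals(matrix)
    groups: dict[str, list[int]] = {}
    for strain, total in totals.items():
        groups.setdefault(matrix.branch_of[strain], []).append(total)
    return {
        g: {"raw": sum(v) / len(v),
            "rounded": _round_half_up(sum(v) / len(v)),
            "n": len(v)}
        for g, v in sorted(groups.items())
    }


def preference_order(matrix: PhenotypeMatrix) -> list[str]:
    """Sugars sorted by positive count, descending; ties keep column order."""
    counts = matrix.values.sum(axis=0)
    order = sorted(range(len(counts)), key=lambda i: -int(counts.iloc[i]))
    return [matrix.sugar_ids[i] for i in order]  # sorted() is stable


def summarize(matrix: PhenotypeMatrix,
              bin_edges: list[int] | None = (5, 10)) -> UsageSummary:
    """One-call summary used by the CLI; bins default to <=4 / 5-9 / >=10."""
    counts, percent = substrate_usage(matrix)
    summary = UsageSummary(
        sugar_counts=counts,
        sugar_percent=percent,
        strain_totals=strain_totals(matrix),
        preference_order=preference_order(matrix),
    )
    if bin_edges:
        summary.bins = bin_strain_totals(matrix, list(bin_edges))
    if matrix.branch_of is not None:
        summary.group_mean = group_mean_usage(matrix)
    return summary
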