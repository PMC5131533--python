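"""Boolean pathway-completeness logic.

A pathway model is a monotone OR-of-AND rule: the phenotype is predicted
POSITIVE when at least one route is satisfied, and a route is satisfied when
every one of its isoform groups contains at least one functional gene. The
module evaluates such rules against gene-state matrices, scores them against
observed phenotypes, detects isoform complementation ("rescue") events, and
infers rules by exhaustive enumeration of monotone DNFs within explicit size
bounds — determinism and completeness are preferred over heuristics at the
problem sizes involved (tens of strains, a handful of candidate genes).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .datamodel import (FunctionalityPolicy, GeneStateMatrix, PathwayModel,
                        Phenotype, PhenotypeMatrix)

__all__ = ["RuleEvaluation", "ConcordanceReport", "RescueEvent",
           "InferredRuleSet", "predict", "concordance",
           "detect_complementation", "infer_rules", "training_accuracy",
           "is_minimal"]

MAX_RULE_EVALUATIONS = 10_000_000


@dataclass
class RuleEvaluation:
    """Per-strain outcome of evaluating a pathway model."""

    strain: str
    sugar: str
    predicted: Phenotype
    active_routes: list[int]
    # for each unsatisfied route index, the first unsatisfied isoform group
    blocking: dict[int, frozenset[str]]


@dataclass
class ConcordanceReport:
    """Confusion counts of rule predictions against observed phenotypes."""

    sugar: str
    tp: int
    fp: int
    fn: int
    tn: int
    discordant: list[tuple[str, str]]  # (strain, "FP" | "FN")
    n_indeterminate_excluded: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")


@dataclass(frozen=True)
class RescueEvent:
    strain: str
    group: frozenset[str]
    primary: str
    rescuers: tuple[str, ...]


def _functional_lookup(genes: GeneStateMatrix, needed: Iterable[str],
                       policy: FunctionalityPolicy) -> dict[str, dict[str, bool]]:
    missing = sorted(set(needed) - set(genes.gene_ids))
    if missing:
        raise KeyError(f"model references genes absent from the gene-state "
                       f"matrix: {missing}")
    return {
        g: {s: policy.is_functional(genes.state(s, g), g)
            for s in genes.strain_ids}
        for g in set(needed)
    }


def predict(genes: GeneStateMatrix, model: PathwayModel,
            policy: FunctionalityPolicy | None = None) -> list[RuleEvaluation]:
    """Evaluate a pathway model for every strain of the matrix."""
    if policy is None:
        policy = FunctionalityPolicy.default_policy()
    func = _functional_lookup(genes, model.genes(), policy)
    out = []
    for strain in genes.strain_ids:
        active, blocking = [], {}
        for i, route in enumerate(model.routes):
            block = next((grp for grp in route
                          if not any(func[g][strain] for g in grp)), None)
            if block is None:
                active.append(i)
            else:
                blocking[i] = block
        out.append(RuleEvaluation(
            strain=strain, sugar=model.sugar,
            predicted=Phenotype.POSITIVE if active else Phenotype.NEGATIVE,
            active_routes=active, blocking=blocking))
    return out


def concordance(predictions: Sequence[RuleEvaluation],
                phenotypes: PhenotypeMatrix, sugar: str) -> ConcordanceReport:
    """Confusion counts over the strains shared by predictions and panel."""
    observed = phenotypes.values[sugar] if sugar in phenotypes.sugar_ids else None
    if observed is None:
        raise KeyError(f"sugar {sugar!r} not in phenotype matrix")
    strains = set(phenotypes.strain_ids)
    tp = fp = fn = tn = 0
    discordant = []
    for ev in predictions:
        if ev.strain not in strains:
            continue
        obs_pos = bool(observed.at[ev.strain])
        pred_pos = ev.predicted is Phenotype.POSITIVE
        if pred_pos and obs_pos:
            tp += 1
        elif pred_pos:
            fp += 1
            discordant.append((ev.strain, "FP"))
        elif obs_pos:
            fn += 1
            discordant.append((ev.strain, "FN"))
        else:
            tn += 1
    return ConcordanceReport(sugar=sugar, tp=tp, fp=fp, fn=fn, tn=tn,
                             discordant=discordant)


def detect_complementation(genes: GeneStateMatrix, phenotypes: PhenotypeMatrix,
                           sugar: str,
                           isoform_groups: Sequence[Sequence[str]],
                           policy: FunctionalityPolicy | None = None
                           ) -> tuple[list[RescueEvent], list[str]]:
    """Find isoform rescue events.

    Each isoform group lists its genes with the primary gene first. A rescue
    event is a phenotype-positive strain in which the primary gene is
    non-functional but another group member is functional. Positive strains
    whose primary is non-functional with no functional rescuer are returned
    separately as unexplained positives.
    """
    if policy is None:
        policy = FunctionalityPolicy.default_policy()
    needed = [g for grp in isoform_groups for g in grp]
    func = _functional_lookup(genes, needed, policy)
    shared = [s for s in genes.strain_ids if s in set(phenotypes.strain_ids)]
    events, unexplained = [], []
    for grp in isoform_groups:
        primary, rest = grp[0], list(grp[1:])
        for strain in shared:
            if not phenotypes.values.at[strain, sugar]:
                continue
            if func[primary][strain]:
                continue
            rescuers = tuple(g for g in rest if func[g][strain])
            if rescuers:
                events.append(RescueEvent(strain=strain,
                                          group=frozenset(grp),
                                          primary=primary,
                                          rescuers=rescuers))
            else:
                unexplained.append(strain)
    return events, unexplained


# ---------------------------------------------------------------------------
# rule inference by exhaustive enumeration


@dataclass
class InferredRuleSet:
    """All maximal-concordance minimal rules found within the search bounds."""

    sugar: str
    rules: list[PathwayModel]
    best_accuracy: float
    majority_accuracy: float
    n_rules_evaluated: int
    low_confidence: bool = False
    bounds: dict = field(default_factory=dict)

    def contains(self, model: PathwayModel) -> bool:
        target = model.routes
        return any(r.routes == target for r in self.rules)


def _route_mask(route: Sequence[frozenset[str]],
                gene_masks: dict[str, int], full: int) -> int:
    mask = full
    for grp in route:
        gm = 0
        for g in grp:
            gm |= gene_masks[g]
        mask &= gm
    return mask


def _rule_accuracy(routes: Sequence[Sequence[frozenset[str]]],
                   gene_masks: dict[str, int], full: int, phen: int,
                   n: int) -> float:
    mask = 0
    for route in routes:
        mask |= _route_mask(route, gene_masks, full)
    return (full & ~(mask ^ phen)).bit_count() / n


def _deletions(routes: tuple[tuple[frozenset[str], ...], ...]):
    """Single-deletion neighbours: drop a route, a group, or one gene.

    Dropping a gene from a singleton group leaves an empty conjunct, which
    makes the route unsatisfiable; that variant is represented by dropping
    the route, which is already enumerated.
    """
    routes_l = [list(r) for r in routes]
    for i in range(len(routes_l)):
        yield tuple(tuple(r) for j, r in enumerate(routes_l) if j != i)
    for i, route in enumerate(routes_l):
        for j, grp in enumerate(route):
            shrunk = [g for k, g in enumerate(route) if k != j]
            yield tuple(tuple(shrunk) if k == i else tuple(r)
                        for k, r in enumerate(routes_l))
            if len(grp) > 1:
                for gene in grp:
                    smaller = grp - {gene}
                    new_route = [smaller if k == j else g
                                 for k, g in enumerate(route)]
                    yield tuple(tuple(new_route) if k == i else tuple(r)
                                for k, r in enumerate(routes_l))


def infer_rules(genes: GeneStateMatrix, phenotypes: PhenotypeMatrix,
                sugar: str, candidates: Sequence[str],
                max_routes: int = 2, max_groups_per_route: int = 2,
                max_group_size: int = 1,
                policy: FunctionalityPolicy | None = None) -> InferredRuleSet:
    """Exhaustively enumerate bounded monotone DNF rules and keep the best.

    Enumerates every rule with up to ``max_routes`` routes, each a conjunction
    of up to ``max_groups_per_route`` isoform groups of up to
    ``max_group_size`` candidate genes (plus the always-false empty rule and
    the always-true empty route). Returns every rule achieving maximal
    concordance with the observed phenotype, filtered to minimal rules: a rule
    is minimal when deleting any single route, isoform group or gene strictly
    decreases training accuracy. Rules are ordered by (number of literals,
    lexicographic gene ids). Raises when the enumeration would exceed
    ``MAX_RULE_EVALUATIONS``.
    """
    if not candidates:
        raise ValueError("no candidate genes given")
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate genes")
    if policy is None:
        policy = FunctionalityPolicy.default_policy()
    func = _functional_lookup(genes, candidates, policy)
    shared = [s for s in genes.strain_ids if s in set(phenotypes.strain_ids)]
    if not shared:
        raise ValueError("gene and phenotype matrices share no strains")
    n = len(shared)
    full = (1 << n) - 1
    gene_masks = {
        g: sum(1 << i for i, s in enumerate(shared) if func[g][s])
        for g in candidates
    }
    phen = sum(1 << i for i, s in enumerate(shared)
               if phenotypes.values.at[s, sugar])

    groups = [frozenset(c) for size in range(1, max_group_size + 1)
              for c in itertools.combinations(sorted(candidates), size)]
    routes = [tuple()]  # the always-true route
    routes += [tuple(c) for size in range(1, max_groups_per_route + 1)
               for c in itertools.combinations(groups, size)]

    n_rules = sum(_ncomb(len(routes), r) for r in range(max_routes + 1))
    if n_rules > MAX_RULE_EVALUATIONS:
        raise ValueError(
            f"search would evaluate {n_rules} rules "
            f"(> {MAX_RULE_EVALUATIONS}); tighten the bounds")

    route_masks = [_route_mask(r, gene_masks, full) for r in routes]
    best_acc = -1.0
    best: list[tuple[tuple, int]] = []
    n_eval = 0
    for r in range(max_routes + 1):
        for combo in itertools.combinations(range(len(routes)), r):
            n_eval += 1
            mask = 0
            for idx in combo:
                mask |= route_masks[idx]
            acc = (full & ~(mask ^ phen)).bit_count() / n
            if acc > best_acc + 1e-12:
                best_acc = acc
                best = [(combo, mask)]
            elif acc >= best_acc - 1e-12:
                best.append((combo, mask))

    # minimality filter on the maximal-concordance rules
    minimal: dict[tuple, PathwayModel] = {}
    for combo, _mask in best:
        rule_routes = tuple(routes[i] for i in combo)
        if all(_rule_accuracy(d, gene_masks, full, phen, n) < best_acc - 1e-12
               for d in _deletions(rule_routes)):
            model = PathwayModel(sugar=sugar, routes=rule_routes,
                                 name="inferred")
            minimal[model.routes] = model

    ordered = sorted(minimal.values(),
                     key=lambda m: (m.n_literals(),
                                    [[sorted(g) for g in r]
                                     for r in m.routes]))
    pos = phen.bit_count()
    majority = max(pos, n - pos) / n
    return InferredRuleSet(
        sugar=sugar, rules=ordered, best_accuracy=best_acc,
        majority_accuracy=majority, n_rules_evaluated=n_eval,
        low_confidence=best_acc <= majority + 1e-12,
        bounds={"max_routes": max_routes,
                "max_groups_per_route": max_groups_per_route,
                "max_group_size": max_group_size})


def _ncomb(n: int, k: int) -> int:
    import math
    return math.comb(n, k)


def _masks_for(genes: GeneStateMatrix, phenotypes: PhenotypeMatrix,
               sugar: str, needed: Iterable[str],
               policy: FunctionalityPolicy | None):
    if policy is None:
        policy = FunctionalityPolicy.default_policy()
    func = _functional_lookup(genes, needed, policy)
    shared = [s for s in genes.strain_ids if s in set(phenotypes.strain_ids)]
    n = len(shared)
    full = (1 << n) - 1
    gene_masks = {g: sum(1 << i for i, s in enumerate(shared) if func[g][s])
                  for g in func}
    phen = sum(1 << i for i, s in enumerate(shared)
               if phenotypes.values.at[s, sugar])
    return gene_masks, full, phen, n


def training_accuracy(genes: GeneStateMatrix, phenotypes: PhenotypeMatrix,
                      model: PathwayModel,
                      policy: FunctionalityPolicy | None = None) -> float:
    """Fraction of shared strains whose observed phenotype the rule matches."""
    gene_masks, full, phen, n = _masks_for(
        genes, phenotypes, model.sugar, model.genes(), policy)
    return _rule_accuracy(model.routes, gene_masks, full, phen, n)


def is_minimal(genes: GeneStateMatrix, phenotypes: PhenotypeMatrix,
               model: PathwayModel,
               policy: FunctionalityPolicy | None = None) -> bool:
    """True when every single deletion strictly decreases training accuracy."""
    gene_masks, full, phen, n = _masks_for(
        genes, phenotypes, model.sugar, model.genes(), policy)
    acc = _rule_accuracy(model.routes, gene_masks, full, phen, n)
    return all(
        _rule_accuracy(d, gene_masks, full, phen, n) < acc - 1e-12
        for d in _deletions(model.routes))
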