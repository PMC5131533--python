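"""Fermentation stoichiometry: end-product yields per mol hexose.

Heterofermentative lactic acid bacteria oxidize hexoses through the
phosphoketolase pathway (1 lactate + 1 ethanol + 1 CO2 per hexose, or — with
fructose serving as the electron acceptor and being reduced to mannitol — the
classic dismutation 3 fructose -> 1 lactate + 1 acetate + 2 mannitol + 1 CO2).
Strains that phosphorylate fructose to fructose-1-P instead feed the
Embden-Meyerhof pathway and ferment homolactically (2 lactate per hexose).
Observed product profiles are modelled as convex mixtures of these route
vectors; fitting the mixture fraction formalizes the argument that an
intermediate lactate yield (e.g. 1.5 mol/mol) reflects both routes running in
parallel.

All yields are expressed per mol of substrate consumed. Product axes are
ordered (lactate, acetate, ethanol, mannitol, CO2); CO2 is carried for carbon
bookkeeping but is typically not measured by HPLC, and unmeasured axes are
masked out of fits rather than assumed zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PRODUCTS", "RouteStoichiometry", "FermentationProfile",
           "FluxSplit", "builtin_routes", "predict_yields", "fit_split",
           "classify_mode"]

PRODUCTS = ("lactate", "acetate", "ethanol", "mannitol", "CO2")

# carbons per molecule, used by the registration balance check
_CARBONS = {"lactate": 3, "acetate": 2, "ethanol": 2, "mannitol": 6, "CO2": 1}
_SUBSTRATE_CARBONS = {"fructose": 6, "glucose": 6, "hexose": 6, "mannose": 6}


@dataclass(frozen=True)
class RouteStoichiometry:
    """Fixed yield vector (mol product per mol substrate) of one route."""

    name: str
    substrate: str
    yields: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.yields) - set(PRODUCTS)
        if unknown:
            raise ValueError(f"unknown products {sorted(unknown)}")
        if any(v < 0 for v in self.yields.values()):
            raise ValueError("yields must be non-negative")
        carbons = _SUBSTRATE_CARBONS.get(self.substrate)
        if carbons is not None:
            total = sum(_CARBONS[p] * v for p, v in self.yields.items())
            if abs(total - carbons) > 1e-9:
                raise ValueError(
                    f"route {self.name!r} is not carbon-balanced: "
                    f"{total} product carbons vs {carbons} substrate carbons")

    def vector(self) -> np.ndarray:
        return np.array([self.yields.get(p, 0.0) for p in PRODUCTS])


@dataclass(frozen=True)
class FermentationProfile:
    """Observed product yields per mol substrate for one strain.

    ``yields`` may omit unmeasured products (they are masked in fits, not
    assumed zero). ``upper_bounds`` lists products reported only as "less
    than" the stored value: they contribute residual only when the prediction
    exceeds the bound.
    """

    strain: str
    substrate: str
    yields: dict[str, float]
    upper_bounds: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.yields) - set(PRODUCTS)
        if unknown:
            raise ValueError(f"unknown products {sorted(unknown)}")
        if any(v < 0 for v in self.yields.values()):
            raise ValueError("yields must be non-negative")
        if not set(self.upper_bounds) <= set(self.yields):
            raise ValueError("upper_bounds must refer to measured products")


@dataclass
class FluxSplit:
    """Non-negative route fractions summing to 1, plus the fit residual."""

    fractions: dict[str, float]
    residual: float = 0.0

    def __post_init__(self) -> None:
        if any(f < -1e-12 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")


def builtin_routes() -> dict[str, RouteStoichiometry]:
    """The three canonical hexose fermentation routes.

    EMP_homolactic: glycolysis, 2 lactate. PK_ethanol: phosphoketolase with
    ethanol as the reduced end product, 1 lactate + 1 ethanol + 1 CO2.
    PK_mannitol_sink: phosphoketolase with fructose as electron acceptor,
    3 fructose -> 1 lactate + 1 acetate + 2 mannitol + 1 CO2, stored per mol.
    """
    return {
        "EMP_homolactic": RouteStoichiometry(
            "EMP_homolactic", "fructose", {"lactate": 2.0}),
        "PK_ethanol": RouteStoichiometry(
            "PK_ethanol", "hexose",
            {"lactate": 1.0, "ethanol": 1.0, "CO2": 1.0}),
        "PK_mannitol_sink": RouteStoichiometry(
            "PK_mannitol_sink", "fructose",
            {"lactate": 1 / 3, "acetate": 1 / 3, "mannitol": 2 / 3,
             "CO2": 1 / 3}),
    }


def predict_yields(split: FluxSplit,
                   routes: dict[str, RouteStoichiometry] | None = None
                   ) -> dict[str, float]:
    """Product yields of a convex mixture of routes, per mol substrate."""
    if routes is None:
        routes = builtin_routes()
    missing = set(split.fractions) - set(routes)
    if missing:
        raise KeyError(f"unknown routes {sorted(missing)}")
    vec = np.zeros(len(PRODUCTS))
    for name, frac in split.fractions.items():
        vec += frac * routes[name].vector()
    return dict(zip(PRODUCTS, vec.tolist()))


def _residual(pred: np.ndarray, obs: np.ndarray, mask: np.ndarray,
              upper: np.ndarray) -> float:
    diff = pred - obs
    # "less than x" observations only penalize predictions above x
    diff = np.where(upper, np.maximum(diff, 0.0), diff)
    return float(np.sqrt(np.sum((diff[mask]) ** 2)))


def fit_split(profile: FermentationProfile,
              routes: dict[str, RouteStoichiometry] | None = None,
              resolution: float = 0.001) -> FluxSplit:
    """Least-squares route fractions on the simplex, by grid search.

    The simplex is scanned at the given resolution (supported for up to three
    routes); unmeasured product axes contribute nothing to the residual and
    CO2 is never fitted. Ties are broken toward the split with the highest
    EMP_homolactic fraction, then lexicographically by the remaining
    fractions, so results are deterministic.
    """
    if routes is None:
        routes = builtin_routes()
    if not routes:
        raise ValueError("need at least one route")
    if not profile.yields:
        raise ValueError("empty profile: no measured products")
    names = sorted(routes, key=lambda r: (r != "EMP_homolactic", r))
    if len(names) > 3:
        raise ValueError("grid-search fitting supports at most 3 routes")
    mats = np.stack([routes[r].vector() for r in names])
    mask = np.array([(p in profile.yields) and p != "CO2" for p in PRODUCTS])
    if not mask.any():
        raise ValueError("profile measures no fittable product")
    obs = np.array([profile.yields.get(p, 0.0) for p in PRODUCTS])
    upper = np.array([p in profile.upper_bounds for p in PRODUCTS])

    steps = int(round(1.0 / resolution))
    best: tuple[float, tuple[float, ...]] | None = None
    if len(names) == 1:
        grid = iter([(steps,)])
    elif len(names) == 2:
        grid = ((i, steps - i) for i in range(steps + 1))
    else:
        grid = ((i, j, steps - i - j) for i in range(steps + 1)
                for j in range(steps + 1 - i))
    for counts in grid:
        fracs = tuple(c / steps for c in counts)
        pred = fracs @ mats
        res = _residual(pred, obs, mask, upper)
        # prefer smaller residual; ties -> larger first (EMP) fraction
        key = (res, tuple(-f for f in fracs))
        if best is None or key < best:
            best = key
            best_fracs = fracs
    return FluxSplit(fractions=dict(zip(names, best_fracs)),
                     residual=best[0])


def classify_mode(profile: FermentationProfile) -> str:
    """Label a profile homolactic-dominant or heterofermentative.

    Homolactic-dominant iff lactate exceeds the sum of acetate, ethanol and
    mannitol (unmeasured products count as zero here); the boundary case is
    heterofermentative.
    """
    lactate = profile.yields.get("lactate", 0.0)
    others = sum(profile.yields.get(p, 0.0)
                 for p in ("acetate", "ethanol", "mannitol"))
    return ("homolactic-dominant" if lactate > others
            else "heterofermentative")
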