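"""Annual lake input-output mass balances.

For every dissolved species the change in lake storage over a year is

    dStorage = sum(outputs) - sum(inputs)

with inputs from exactly three compartments (snowmelt on the lake surface,
snowmelt runoff from the landscape, glacial rivers) and output the export by
the single outflow river. A negative dStorage marks the lake as a net sink,
a positive one as a net source. A budget is called *significant* (and hence
classified sink or source rather than neutral) when the k-sigma intervals of
total inputs and outputs do not overlap.

Standard errors of sums are combined by plain linear addition of component
SEs by default — the conservative convention used in whole-watershed budget
tables where component errors are strongly dependent (they share the same
hydrograph) — with quadrature available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BudgetComponent", "BudgetResult",
    "INPUT_COMPARTMENTS", "sum_inputs", "delta_storage", "classify_budget",
    "glacial_share", "share_range", "outflow_discharge", "assemble_budget",
]

INPUT_COMPARTMENTS = ("snow_on_lake", "snow_from_land", "glacial_rivers")


@dataclass(frozen=True)
class BudgetComponent:
    """One annual load entering or leaving the lake."""

    compartment: str
    species: str
    year: int
    load: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.compartment not in INPUT_COMPARTMENTS + ("outflow",):
            raise ValueError(f"unknown budget compartment {self.compartment!r}")
        if self.load < 0 or self.se < 0:
            raise ValueError("loads and SEs must be >= 0")


@dataclass
class BudgetResult:
    species: str
    year: int
    total_in: float
    se_in: float
    total_out: float
    se_out: float
    delta_storage: float
    classification: str
    percent_difference: float
    glacial_share: float | None


def _check_homogeneous(components: Sequence[BudgetComponent]) -> None:
    if len({(c.species, c.year) for c in components}) > 1:
        raise ValueError("components mix species or years")


def sum_inputs(components: Sequence[BudgetComponent],
               se_combination: str = "linear") -> tuple[float, float]:
    """Total inputs and combined SE over the three input compartments."""
    _check_homogeneous(components)
    comps = {c.compartment for c in components}
    if comps != set(INPUT_COMPARTMENTS):
        raise ValueError(f"expected compartments {INPUT_COMPARTMENTS}, got {sorted(comps)}")
    total = sum(c.load for c in components)
    if se_combination == "linear":
        se = sum(c.se for c in components)
    elif se_combination == "quadrature":
        se = float(np.sqrt(sum(c.se ** 2 for c in components)))
    else:
        raise ValueError("se_combination must be 'linear' or 'quadrature'")
    return float(total), float(se)


def delta_storage(total_in: float, total_out: float) -> float:
    """Outputs minus inputs; negative = net sink, positive = net source."""
    return total_out - total_in


def classify_budget(total_in: float, se_in: float,
                    total_out: float, se_out: float,
                    k: float = 1.0) -> str:
    """Sink/source/neutral by k-sigma interval disjointness.

    Significant (sink or source by the sign of dStorage) when
    ``[out - k se_out, out + k se_out]`` and ``[in - k se_in, in + k se_in]``
    do not overlap; otherwise neutral.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if se_in < 0 or se_out < 0:
        raise ValueError("standard errors must be >= 0")
    disjoint = (total_out + k * se_out < total_in - k * se_in or
                total_out - k * se_out > total_in + k * se_in)
    if not disjoint:
        return "neutral"
    return "source" if total_out > total_in else "sink"


def glacial_share(components: Sequence[BudgetComponent]) -> float | None:
    """Glacial rivers' percentage of total inputs; None for a zero total."""
    _check_homogeneous(components)
    by = {c.compartment: c.load for c in components}
    missing = set(INPUT_COMPARTMENTS) - set(by)
    if missing:
        raise ValueError(f"missing input compartments: {sorted(missing)}")
    total = sum(by[c] for c in INPUT_COMPARTMENTS)
    if total == 0:
        return None
    return 100.0 * by["glacial_rivers"] / total


def share_range(budgets: Iterable[BudgetResult],
                species: Iterable[str] | None = None) -> tuple[float, float]:
    """Extremes of the glacial share across budgets (optionally filtered)."""
    keep = set(species) if species is not None else None
    shares = [b.glacial_share for b in budgets
              if b.glacial_share is not None and (keep is None or b.species in keep)]
    if not shares:
        raise ValueError("no budgets with a defined glacial share")
    return min(shares), max(shares)


def outflow_discharge(glacial_km3: float, snow_on_lake_km3: float,
                      snow_from_land_km3: float) -> float:
    """Outflow volume approximated as the sum of all inflows.

    Valid for a lake that is ice-covered most of the year, where evaporation
    from the lake surface and the rivers is negligible; the assumption is
    the closure of the water balance.
    """
    return glacial_km3 + snow_on_lake_km3 + snow_from_land_km3


def assemble_budget(inputs: Sequence[BudgetComponent],
                    outflow: BudgetComponent,
                    k: float = 1.0,
                    se_combination: str = "linear") -> BudgetResult:
    """Full budget for one species x year from its four components.

    ``percent_difference`` is 100 (out - in)/in — the package's own,
    explicitly documented formula.
    """
    _check_homogeneous(list(inputs) + [outflow])
    if outflow.compartment != "outflow":
        raise ValueError("outflow component must have compartment 'outflow'")
    total_in, se_in = sum_inputs(inputs, se_combination=se_combination)
    ds = delta_storage(total_in, outflow.load)
    cls = classify_budget(total_in, se_in, outflow.load, outflow.se, k=k)
    pct = 100.0 * ds / total_in if total_in > 0 else float("nan")
    return BudgetResult(
        species=outflow.species, year=outflow.year,
        total_in=total_in, se_in=se_in,
        total_out=outflow.load, se_out=outflow.se,
        delta_storage=ds, classification=cls,
        percent_difference=pct, glacial_share=glacial_share(inputs),
    )
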