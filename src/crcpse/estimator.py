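"""Lincoln-Petersen two-source population size estimation.

Given M individuals marked in a first capture round, C individuals seen in
a second round, and R seen in both, the Lincoln-Petersen estimator of a
closed population's size is

    N̂ = M·C / R

with variance  Var(N̂) = M·C·(M−R)·(C−R) / R³  and a normal-approximation
95% interval N̂ ± 1.96·√Var(N̂), truncated below at zero.  All reported
person counts — the point estimate and both interval bounds — are rounded
*up* to the next whole number (a fraction of a person implies at least one
more), matching the convention of the SISA capture-recapture calculator
used in field HIV-surveillance practice.

The estimator is undefined at R = 0; that case raises
:class:`NoRecapturesError` rather than returning infinity, so a pipeline
over many towns can report the town as non-estimable and continue.
Chapman's small-sample variant ((M+1)(C+1)/(R+1) − 1) is provided as an
explicitly optional alternative; it is never used implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

from .records import TownSummary

__all__ = [
    "Estimate",
    "NoRecapturesError",
    "lp_estimate",
    "lp_variance",
    "lp_ci",
    "chapman_estimate",
    "round_up",
    "round_half_up",
    "estimate_town",
    "estimate_all",
    "target_sample_size",
]

Z_95 = 1.96

#: assumed key-population share of the adult population of the relevant sex,
#: used only for planning the number of objects to distribute
PLANNING_FRACTION = {"FSW": Fraction(5, 1000), "MSM": Fraction(15, 1000)}


class NoRecapturesError(ValueError):
    """Raised when R = 0: the Lincoln-Petersen estimator is undefined."""


def _check_mcr(m: int, c: int, r: int) -> None:
    if m < 1 or c < 1:
        raise ValueError(f"M and C must be >= 1 (got M={m}, C={c})")
    if r == 0:
        raise NoRecapturesError("estimator undefined (no recaptures)")
    if r < 0 or r > min(m, c):
        raise ValueError(f"R must satisfy 1 <= R <= min(M, C) (got M={m}, C={c}, R={r})")


def lp_estimate(m: int, c: int, r: int) -> Fraction:
    """Point estimate M·C/R as an exact fraction (no premature rounding)."""
    _check_mcr(m, c, r)
    return Fraction(m * c, r)


def lp_variance(m: int, c: int, r: int) -> Fraction:
    """Variance M·C·(M−R)·(C−R)/R³ of the point estimate, in persons²."""
    _check_mcr(m, c, r)
    return Fraction(m * c * (m - r) * (c - r), r**3)


def round_up(x: float | Fraction) -> int:
    """Smallest integer >= x (the 'next whole number' reporting rule)."""
    if x < 0:
        raise ValueError(f"round_up expects a nonnegative value, got {x}")
    return math.ceil(x)


def round_half_up(x: float | Fraction, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, for printed percentages."""
    q = Fraction(x).limit_denominator(10**12) if isinstance(x, float) else Fraction(x)
    scaled = q * 10**ndigits
    return float(math.floor(scaled + Fraction(1, 2))) / 10**ndigits


def lp_ci(m: int, c: int, r: int, z: float = Z_95) -> tuple[int, int]:
    """Normal 95% interval bounds in whole persons.

    Bounds are N̂ ± z·√Var; a negative lower bound is truncated to 0 before
    rounding, and both bounds are then rounded up to the next whole number.
    """
    n_raw = lp_estimate(m, c, r)
    half = z * math.sqrt(lp_variance(m, c, r))
    lower = max(float(n_raw) - half, 0.0)
    upper = float(n_raw) + half
    return round_up(lower), round_up(upper)


def chapman_estimate(m: int, c: int, r: int) -> Fraction:
    """Chapman's nearly unbiased variant (M+1)(C+1)/(R+1) − 1.

    Defined even at R = 0; offered as an optional extension only — nothing
    in this package falls back to it implicitly.
    """
    if m < 0 or c < 0 or r < 0 or r > min(m, c):
        raise ValueError(f"invalid counts M={m}, C={c}, R={r}")
    return Fraction((m + 1) * (c + 1), r + 1) - 1


@dataclass(frozen=True)
class Estimate:
    """A population size estimate for one town, population and definition."""

    town: str
    population: str
    definition: str
    m: int
    c: int
    r: int
    n_raw: float
    n_hat: int
    variance: float
    ci_lower: int
    ci_upper: int
    adult_population: int | None = None
    prevalence_pct: float | None = None


def estimate_town(summary: TownSummary, definition: str) -> Estimate:
    """Estimate for one town under the chosen recapture definition.

    Prevalence (the estimate as a percentage of the town's adult population
    of the relevant sex) is computed from the rounded estimate and reported
    half-up to 2 decimals; it is ``None`` when no denominator is known.
    Raises :class:`NoRecapturesError` when R = 0 for the chosen definition.
    """
    m, c = summary.n_capture1, summary.n_capture2
    r = summary.recaptures(definition)
    n_raw = lp_estimate(m, c, r)
    n_hat = round_up(n_raw)
    lo, hi = lp_ci(m, c, r)
    prevalence = None
    if summary.adult_population:
        prevalence = round_half_up(Fraction(n_hat * 100, summary.adult_population))
    return Estimate(
        town=summary.town,
        population=summary.population,
        definition=definition,
        m=m, c=c, r=r,
        n_raw=float(n_raw),
        n_hat=n_hat,
        variance=float(lp_variance(m, c, r)),
        ci_lower=lo,
        ci_upper=hi,
        adult_population=summary.adult_population,
        prevalence_pct=prevalence,
    )


def estimate_all(
    summaries: Iterable[TownSummary],
    definitions: Iterable[str] = ("def1", "def2"),
) -> tuple[list[Estimate], list[tuple[str, str, str]]]:
    """Estimate every town x definition; towns with R = 0 are collected as
    (town, population, definition) in the second return value instead of
    aborting the run."""
    estimates: list[Estimate] = []
    not_estimable: list[tuple[str, str, str]] = []
    for s in summaries:
        for d in definitions:
            try:
                estimates.append(estimate_town(s, d))
            except NoRecapturesError:
                not_estimable.append((s.town, s.population, d))
    return estimates, not_estimable


def target_sample_size(adult_population: int, population: str) -> int:
    """Planning-stage number of objects to distribute in a town.

    Assumes 0.5% of adult women are sex workers and 1.5% of adult men are
    men who have sex with men; the target is that share of the denominator,
    rounded up.
    """
    if adult_population < 0:
        raise ValueError("adult_population must be nonnegative")
    try:
        frac = PLANNING_FRACTION[population]
    except KeyError:
        raise ValueError(f"unknown population category {population!r}") from None
    return round_up(frac * adult_population)
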