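"""Data-quality diagnostics for two-source capture-recapture field data.

Three families of checks, all report-only (nothing here alters counts or
estimates):

* per-distributor recapture shares of capture 2, and a flag when one
  distributor accounts for substantially more (>10 percentage points of
  capture 2) recaptures than another — a symptom of unequal effort or
  non-random sampling;
* arithmetic consistency of a town summary (offered − refusals = M,
  definition ordering, distributor sums versus recapture totals);
* plausibility of the implied prevalence against published reference
  bands: 3%–5% of adult men for MSM globally, 0.1%–12.0% of adult women
  for FSWs across African subnational estimates.  Band endpoints are
  inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

from .estimator import Estimate, round_half_up
from .records import TownSummary

__all__ = [
    "DiagnosticsReport",
    "PREVALENCE_BANDS",
    "IMBALANCE_THRESHOLD",
    "distributor_shares",
    "imbalance_flag",
    "consistency_checks",
    "prevalence_band_check",
    "diagnose",
]

#: inclusive plausibility bands, in percent of the adult population
PREVALENCE_BANDS: dict[str, tuple[float, float]] = {
    "MSM": (3.0, 5.0),
    "FSW": (0.1, 12.0),
}

#: flag when two distributors' shares of capture 2 differ by more than this
IMBALANCE_THRESHOLD = 0.10


@dataclass(frozen=True)
class DiagnosticsReport:
    town: str
    population: str
    distributor_shares: Mapping[str, float]  # rounded to 2 decimals for display
    imbalance_flag: bool
    refusal_rate: float | None
    consistency_violations: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()
    prevalence_flags: Mapping[str, str] = field(default_factory=dict)


def distributor_shares(summary: TownSummary, *, rounded: bool = True) -> dict[str, float]:
    """Each distributor's recaptures as a share of capture 2.

    Shares are reported half-up to 2 decimals by default; pass
    ``rounded=False`` for the exact values (used by the imbalance flag).
    Raises ``ValueError`` when capture 2 is empty (share undefined).
    """
    if summary.n_capture2 < 1:
        raise ValueError(f"{summary.town}/{summary.population}: no capture-2 events; shares undefined")
    shares = {
        d: Fraction(n, summary.n_capture2)
        for d, n in summary.distributor_recaptures.items()
    }
    if rounded:
        return {d: round_half_up(v) for d, v in shares.items()}
    return {d: float(v) for d, v in shares.items()}


def imbalance_flag(shares: Mapping[str, float], threshold: float = IMBALANCE_THRESHOLD) -> bool:
    """True iff the largest pairwise share difference exceeds the threshold.

    Symmetric in distributor labels.  With fewer than two distributors the
    comparison is undefined and the flag is False.
    """
    if len(shares) < 2:
        return False
    values = list(shares.values())
    return (max(values) - min(values)) > threshold


def consistency_checks(summary: TownSummary) -> tuple[list[str], list[str]]:
    """Arithmetic identities a clean summary must satisfy.

    Returns ``(violations, notes)``.  Violations are logically impossible
    states (definition-2 recaptures exceeding definition-1, recaptures
    exceeding a capture total).  Notes are reconciliation failures that
    occur in real transcribed data — e.g. per-distributor recapture counts
    whose sum matches neither recapture definition — reported but never
    corrected.
    """
    violations: list[str] = []
    notes: list[str] = []
    s = summary
    if s.objects_offered - s.refusals != s.n_capture1:
        # occurs in transcribed field tables; reported, never corrected
        notes.append(
            f"offered-refusals mismatch: {s.objects_offered}-{s.refusals} != {s.n_capture1}")
    if s.recaptures_def2 > s.recaptures_def1:
        violations.append(
            f"def2 recaptures ({s.recaptures_def2}) exceed def1 ({s.recaptures_def1})")
    if s.recaptures_def1 > min(s.n_capture1, s.n_capture2):
        violations.append(
            f"def1 recaptures ({s.recaptures_def1}) exceed min(M, C) "
            f"= {min(s.n_capture1, s.n_capture2)}")
    if s.recaptures_def1 + s.misidentified > s.n_capture2:
        violations.append(
            f"recaptures + misidentifications ({s.recaptures_def1}+{s.misidentified}) "
            f"exceed capture 2 ({s.n_capture2})")
    if s.distributor_recaptures:
        total = sum(s.distributor_recaptures.values())
        if total > s.n_capture2:
            violations.append(
                f"distributor recaptures ({total}) exceed capture 2 ({s.n_capture2})")
        elif total not in (s.recaptures_def1, s.recaptures_def2):
            detail = "+".join(str(v) for v in s.distributor_recaptures.values())
            notes.append(
                f"distributor recapture sum {detail}={total} matches neither "
                f"def1={s.recaptures_def1} nor def2={s.recaptures_def2}")
    return violations, notes


def prevalence_band_check(estimate: Estimate) -> str:
    """Classify an estimate's prevalence against the reference band.

    Returns ``below_band``, ``in_band``, ``above_band`` or ``no_band``
    (no denominator, or no published band for the population group).
    """
    if estimate.prevalence_pct is None:
        return "no_band"
    band = PREVALENCE_BANDS.get(estimate.population)
    if band is None:
        return "no_band"
    lo, hi = band
    if estimate.prevalence_pct < lo:
        return "below_band"
    if estimate.prevalence_pct > hi:
        return "above_band"
    return "in_band"


def diagnose(summary: TownSummary, estimates: Mapping[str, Estimate] | None = None) -> DiagnosticsReport:
    """Full report for one town: shares, imbalance, refusal rate,
    consistency results and (when estimates are supplied per definition)
    prevalence band classifications."""
    violations, notes = consistency_checks(summary)
    if summary.n_capture2 >= 1 and summary.distributor_recaptures:
        exact = distributor_shares(summary, rounded=False)
        shares = distributor_shares(summary)
        flag = imbalance_flag(exact)
        if len(exact) < 2:
            notes = [*notes, "single distributor: imbalance flag undefined, reported as False"]
    else:
        exact, shares, flag = {}, {}, False
        notes = [*notes, "no capture-2 distributor data: shares undefined"]
    refusal_rate = (
        summary.refusals / summary.objects_offered if summary.objects_offered else None
    )
    prevalence_flags = {
        d: prevalence_band_check(est) for d, est in (estimates or {}).items()
    }
    return DiagnosticsReport(
        town=summary.town,
        population=summary.population,
        distributor_shares=shares,
        imbalance_flag=flag,
        refusal_rate=refusal_rate,
        consistency_violations=tuple(violations),
        notes=tuple(notes),
        prevalence_flags=prevalence_flags,
    )
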