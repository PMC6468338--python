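"""Packaged town-level count data from a two-source capture-recapture
exercise among female sex workers (11 towns) and men who have sex with men
(7 towns) in Uganda, June-August 2017.

Each row carries the published per-town counts: objects offered, refusals,
capture-1 and capture-2 totals, recaptures under both definitions,
misidentifications, per-distributor recapture counts, and the adult
population denominator of the relevant sex.  The per-distributor counts are
transcribed as published; in two towns (Busia and Mukono, FSW) their sum
matches neither recapture definition — a recorded inconsistency of the
source data that diagnostics report and nothing corrects.
"""

from __future__ import annotations

from importlib import resources

from .records import TownSummary, read_summary

__all__ = ["load_uganda_summaries", "uganda_denominators"]

_FILES = {"FSW": "uganda_fsw_summary.csv", "MSM": "uganda_msm_summary.csv"}


def load_uganda_summaries(population: str | None = None) -> list[TownSummary]:
    """Load the packaged Ugandan town summaries.

    ``population`` restricts to "FSW" or "MSM"; by default both groups are
    returned (11 FSW + 7 MSM rows).
    """
    if population is not None and population not in _FILES:
        raise ValueError(f"unknown population {population!r}")
    names = [_FILES[population]] if population else list(_FILES.values())
    out: list[TownSummary] = []
    for name in names:
        ref = resources.files("crcpse.data").joinpath(name)
        with ref.open("r", encoding="utf-8") as fh:
            out.extend(read_summary(fh))
    return out


def uganda_denominators() -> dict[tuple[str, str], int]:
    """(town, population) -> adult population of the relevant sex."""
    return {
        (s.town, s.population): s.adult_population
        for s in load_uganda_summaries()
        if s.adult_population is not None
    }
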