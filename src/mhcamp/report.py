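"""Bookkeeping percentages for filter and run reports.

These helpers centralise the percentage arithmetic quoted in run reports:
retention through a filtering step, the chimera share of candidates, the
singleton share of reads, and tag-space/misassignment summaries.
"""

from __future__ import annotations

__all__ = [
    "percentage",
    "retention_percent",
    "chimera_percent",
    "singleton_percent",
]


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return round(100.0 * numerator / denominator, ndigits)


def retention_percent(n_retained: int, n_candidates: int, ndigits: int = 1) -> float:
    """Share of candidate variants surviving a filtering step."""
    return percentage(n_retained, n_candidates, ndigits)


def chimera_percent(n_chimeras: int, n_candidates: int, ndigits: int = 1) -> float:
    """Share of candidates classified as PCR chimeras."""
    return percentage(n_chimeras, n_candidates, ndigits)


def singleton_percent(n_singletons: int, n_reads: int, ndigits: int = 1) -> float:
    """Share of all reads that are dataset-wide singleton sequences."""
    return percentage(n_singletons, n_reads, ndigits)
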