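"""Descriptive summaries and ranked drug tables over a screened cohort.

Percentages are rounded half-up at one decimal, the convention of printed
safety tables.  For most categories the denominator is the full cohort; for
reporter country the published convention divides by reports with a known
country, so that mode is the country default (both are selectable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up

logger = logging.getLogger("pvscreen.screen")

__all__ = [
    "DemographicSummary",
    "SUPPORTED_CATEGORIES",
    "percentage",
    "summarize_demographics",
    "rank_top_drugs",
    "forest_table",
]

#: category name -> cohort column
SUPPORTED_CATEGORIES = {
    "age_group": "age_group",
    "sex": "sex",
    "reporter": "reporter",
    "outcome": "outcomes",
    "country": "country",
    "year": "year",
}

#: categories whose published percentages use the known-value denominator
_DEFAULT_KNOWN = {"country"}

#: most-serious-first priority used to assign one outcome per report
_OUTCOME_PRIORITY = [
    "death",
    "life-threatening",
    "hospitalization",
    "disability",
    "congenital-anomaly",
    "other-serious",
]

_LEVEL_ORDER = {
    "age_group": ["<18", "18-64", "65-85", ">85", "unknown"],
    "sex": ["M", "F", "unknown"],
    "outcome": _OUTCOME_PRIORITY + ["unknown"],
}


@dataclass
class DemographicSummary:
    category: str
    level: str
    count: int
    pct: float
    denominator: int


def percentage(count: int, denominator: int) -> float:
    """100 * count / denominator, rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * count / denominator, 1)


def _primary_outcome(joined: str) -> str:
    """Single most-serious outcome of a report (its outcomes are a set)."""
    present = set(joined.split("|")) if joined else set()
    for level in _OUTCOME_PRIORITY:
        if level in present:
            return level
    return "unknown"


def summarize_demographics(
    cohort: pd.DataFrame, category: str, denominator_mode: str | None = None
) -> pd.DataFrame:
    """Counts and percentages of one demographic category.

    Parameters
    ----------
    cohort
        Deduplicated cohort frame.
    category
        One of ``age_group``, ``sex``, ``reporter``, ``outcome``,
        ``country``, ``year``.  Reports with several outcome codes are
        summarized under their single most serious one so the counts
        partition the cohort.
    denominator_mode
        ``"total"`` divides by the cohort size, ``"known"`` by the cohort
        minus unknown-level reports.  Default: ``known`` for country,
        ``total`` otherwise.
    """
    if category not in SUPPORTED_CATEGORIES:
        raise ValueError(
            f"unsupported category {category!r}; supported: "
            + ", ".join(sorted(SUPPORTED_CATEGORIES))
        )
    if denominator_mode is None:
        denominator_mode = "known" if category in _DEFAULT_KNOWN else "total"
    if denominator_mode not in ("total", "known"):
        raise ValueError("denominator_mode must be 'total' or 'known'")

    col = SUPPORTED_CATEGORIES[category]
    values = cohort[col]
    if category == "outcome":
        values = values.map(_primary_outcome)
    elif category == "year":
        values = values.astype(int).astype(str).replace("0", "unknown")
    counts = values.value_counts()

    n_total = len(cohort)
    denominator = n_total
    if denominator_mode == "known":
        denominator = n_total - int(counts.get("unknown", 0))

    order = _LEVEL_ORDER.get(category)
    if order is not None:
        levels = [lv for lv in order if lv in counts.index]
        levels += [lv for lv in counts.index if lv not in order]
    else:
        known = counts.drop("unknown", errors="ignore")
        levels = list(known.sort_values(ascending=False).index)
        if "unknown" in counts.index:
            levels.append("unknown")

    rows = []
    for level in levels:
        count = int(counts[level])
        if denominator_mode == "known" and level == "unknown":
            pct = float("nan")
        else:
            pct = percentage(count, denominator)
        rows.append(
            {
                "category": category,
                "level": level,
                "count": count,
                "pct": pct,
                "denominator": denominator,
            }
        )
    return pd.DataFrame(rows, columns=["category", "level", "count", "pct", "denominator"])


def rank_top_drugs(results: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k drugs by co-report count, ties broken alphabetically.

    ``results`` is the disproportionality results frame; the output keeps
    every statistic column, adds ``rank`` (1-based, consecutive) and carries
    ``is_signal`` so "m of k positive" is a one-liner.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(results):
        logger.warning("requested top %d of only %d drugs; returning all", k, len(results))
        k = len(results)
    ranked = (
        results.sort_values(["n", "drug"], ascending=[False, True], kind="stable")
        .head(k)
        .reset_index(drop=True)
    )
    ranked.insert(0, "rank", range(1, len(ranked) + 1))
    return ranked


def forest_table(results: pd.DataFrame) -> pd.DataFrame:
    """The forest-plot table: drug with ROR point estimate and CI bounds."""
    return results[["drug", "ror", "ror_lo", "ror_hi"]].copy()
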