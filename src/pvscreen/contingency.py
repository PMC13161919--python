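"""Build 2x2 drug-event contingency tables over a deduplicated cohort.

The counting unit is the deduplicated report: a report contributes to the
"drug" margin iff it carries at least one drug row whose normalized name
matches and whose role code is in the requested filter, and it contributes
exactly once however many matching rows it carries.  The four cells
partition the cohort, so a + b + c + d = N for every drug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger("pvscreen.contingency")

__all__ = [
    "ContingencyTable",
    "DEFAULT_ROLE_FILTER",
    "build_contingency",
    "build_all_pairs",
    "read_tables",
    "write_tables",
]

#: Suspect drugs only (primary + secondary suspect); pass ``None`` for all roles.
DEFAULT_ROLE_FILTER = frozenset({"PS", "SS"})

TABLE_COLUMNS = ["drug", "a", "b", "c", "d", "N"]


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of one drug-event 2x2 table.

    a: reports with the drug and the target event; b: drug, no event;
    c: event, no drug; d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a-cell under independence of margins: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.N


def _require_standardized(cohort: pd.DataFrame) -> None:
    if "drugs_norm" not in cohort.columns or "is_target_event" not in cohort.columns:
        raise ValueError("cohort must be standardized (drugs_norm / is_target_event)")
    if (cohort["drugs_norm"] == "").all() and len(cohort):
        raise ValueError("cohort has no normalized drug names; run standardize_terms first")


def _exposure_pairs(cohort: pd.DataFrame, role_filter: Optional[Iterable[str]]) -> pd.DataFrame:
    """Distinct (report index, drug) pairs surviving the role filter."""
    frame = pd.DataFrame(
        {
            "drug": cohort["drugs_norm"].str.split("|"),
            "role": cohort["drug_roles"].str.split("|"),
        }
    ).explode(["drug", "role"])
    if role_filter is not None:
        frame = frame[frame["role"].isin(set(role_filter))]
    frame = frame[frame["drug"].notna() & (frame["drug"] != "")]
    return frame.reset_index()[["index", "drug"]].drop_duplicates()


def build_contingency(
    cohort: pd.DataFrame,
    drug: str,
    role_filter: Optional[Iterable[str]] = DEFAULT_ROLE_FILTER,
) -> ContingencyTable:
    """2x2 table for one normalized drug name against the target event."""
    _require_standardized(cohort)
    pairs = _exposure_pairs(cohort, role_filter)
    exposed_idx = pairs.loc[pairs["drug"] == drug, "index"]
    if exposed_idx.empty:
        logger.warning("drug %r not present in cohort under the role filter", drug)
    exposed = cohort.index.isin(exposed_idx)
    event = cohort["is_target_event"].to_numpy(dtype=bool)
    a = int((exposed & event).sum())
    b = int((exposed & ~event).sum())
    c = int((~exposed & event).sum())
    d = int((~exposed & ~event).sum())
    return ContingencyTable(a, b, c, d)


def build_all_pairs(
    cohort: pd.DataFrame,
    role_filter: Optional[Iterable[str]] = DEFAULT_ROLE_FILTER,
) -> pd.DataFrame:
    """One 2x2 table per distinct normalized drug, sorted by the a-cell.

    Returns a frame with columns drug, a, b, c, d, N; every row satisfies
    a + b + c + d = N and a + c = total target-event reports.
    """
    if cohort.empty:
        raise ValueError("cannot build contingency tables over an empty cohort")
    _require_standardized(cohort)
    pairs = _exposure_pairs(cohort, role_filter)
    event = cohort["is_target_event"].astype(bool)
    n_total = len(cohort)
    n_event = int(event.sum())

    pairs["event"] = event.reindex(pairs["index"]).to_numpy()
    grouped = pairs.groupby("drug")["event"].agg(["sum", "count"])
    out = pd.DataFrame(
        {
            "drug": grouped.index,
            "a": grouped["sum"].astype(int),
            "b": (grouped["count"] - grouped["sum"]).astype(int),
        }
    ).reset_index(drop=True)
    out["c"] = n_event - out["a"]
    out["d"] = n_total - out["a"] - out["b"] - out["c"]
    out["N"] = n_total
    return (
        out.sort_values(["a", "drug"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)[TABLE_COLUMNS]
    )


def write_tables(tables: pd.DataFrame, path) -> None:
    tables.to_csv(path, sep="\t", index=False)


def read_tables(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"drug": str})
    return df[TABLE_COLUMNS]
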