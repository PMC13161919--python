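"""Ingest FAERS-dialect quarterly ASCII tables into a deduplicated cohort.

The FDA distributes its spontaneous-reporting database (FAERS) as quarterly
``$``-delimited ASCII tables: DEMO (demographics), DRUG, REAC (reactions as
MedDRA preferred terms), OUTC (outcomes), RPSR (report sources), THER
(therapy dates) and INDI (indications).  This module parses that dialect,
joins the tables into one row per report, collapses duplicate case versions
(same CASEID) to the record with the latest receipt date — ties broken by the
higher PRIMARYID — and standardizes free-text drug names and event terms
against user-supplied mapping files.

The in-memory cohort is a :class:`pandas.DataFrame` with one row per report;
list-valued fields (drug rows, reactions, outcomes) are pipe-joined strings so
the cohort round-trips losslessly through a flat tab-separated file.  The
dataclasses :class:`AdverseEventReport` and :class:`DrugRow` give a typed
record view of the same schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("pvscreen.faers_io")

__all__ = [
    "AdverseEventReport",
    "DrugRow",
    "TermMap",
    "FaersFormatError",
    "parse_quarter_tables",
    "deduplicate_reports",
    "standardize_terms",
    "load_term_map",
    "read_cohort",
    "write_cohort",
    "frame_to_reports",
    "COHORT_COLUMNS",
]

# --------------------------------------------------------------------------
# Vocabulary

AGE_GROUPS = ("<18", "18-64", "65-85", ">85", "unknown")
SEXES = ("M", "F", "unknown")
ROLE_CODES = ("PS", "SS", "C", "I")  # primary/secondary suspect, concomitant, interacting

#: occp_cod -> reporter occupation
OCCUPATION_CODES = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other-health-professional",
    "LW": "lawyer",
}
OCCUPATION_TO_CODE = {v: k for k, v in OCCUPATION_CODES.items()}

#: outc_cod -> outcome
OUTCOME_CODES = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital-anomaly",
    "OT": "other-serious",
}
OUTCOME_TO_CODE = {v: k for k, v in OUTCOME_CODES.items()}

#: Hours in a year etc. for age-unit conversion
_AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.0,
    "HR": 1.0 / 8766.0,
}

COHORT_COLUMNS = [
    "primaryid",
    "caseid",
    "fda_dt",
    "age_group",
    "sex",
    "reporter",
    "country",
    "year",
    "outcomes",
    "drugs_raw",
    "drug_roles",
    "drugs_norm",
    "reactions",
    "is_target_event",
    "report_sources",
    "therapy_dates",
    "indications",
]

_TABLE_NAMES = ("demo", "drug", "reac", "outc", "rpsr", "ther", "indi")
_MANDATORY_COLUMNS = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drugname"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "rpsr": ("primaryid", "rpsr_cod"),
    "ther": ("primaryid",),
    "indi": ("primaryid",),
}


class FaersFormatError(ValueError):
    """A quarter file is missing or its header lacks a mandatory column."""


# --------------------------------------------------------------------------
# Domain types


@dataclass
class DrugRow:
    """One drug mention on a report: verbatim string, mapped name, role code."""

    raw_name: str
    normalized_name: str = ""
    role: str = "unknown"


@dataclass
class AdverseEventReport:
    """One (deduplicated) safety report."""

    primaryid: int
    caseid: int
    fda_dt: int
    age_group: str = "unknown"
    sex: str = "unknown"
    reporter: str = "unknown"
    country: str = "unknown"
    outcomes: frozenset = frozenset()
    drugs: list = field(default_factory=list)
    reactions: frozenset = frozenset()
    is_target_event: bool = False

    @property
    def year(self) -> int:
        return self.fda_dt // 10000 if self.fda_dt else 0


@dataclass
class TermMap:
    """Drug-name synonyms plus the preferred-term list defining the target event.

    Lookups are case-insensitive and whitespace-trimmed; each raw string maps
    to exactly one ingredient.
    """

    drug_synonyms: dict
    event_terms: frozenset

    def __post_init__(self) -> None:
        self.drug_synonyms = {
            _key(k): str(v).strip().lower() for k, v in self.drug_synonyms.items()
        }
        self.event_terms = frozenset(_key(t) for t in self.event_terms if str(t).strip())

    def normalize_drug(self, raw: str) -> str:
        """Mapped ingredient for a verbatim drug string, or '' if unmapped."""
        return self.drug_synonyms.get(_key(raw), "")

    def is_target(self, reactions: Iterable[str]) -> bool:
        return any(_key(r) in self.event_terms for r in reactions)


def _key(s: str) -> str:
    return str(s).strip().casefold()


def load_term_map(synonyms_path, event_terms_path) -> TermMap:
    """Load a TermMap from two plain-text files.

    ``synonyms_path`` is tab-separated ``raw<TAB>ingredient`` (one pair per
    line, ``#`` comments allowed); ``event_terms_path`` lists one preferred
    term per line.
    """
    synonyms = {}
    for line in Path(synonyms_path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FaersFormatError(f"synonym line is not raw<TAB>ingredient: {line!r}")
        synonyms[parts[0]] = parts[1]
    terms = [
        t.strip()
        for t in Path(event_terms_path).read_text(encoding="utf-8").splitlines()
        if t.strip() and not t.startswith("#")
    ]
    return TermMap(drug_synonyms=synonyms, event_terms=frozenset(terms))


# --------------------------------------------------------------------------
# Parsing


def _read_table(path, name: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
        encoding_errors="replace",
        engine="python",
    )
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _MANDATORY_COLUMNS[name]:
        if col not in df.columns:
            raise FaersFormatError(
                f"{name.upper()} table {path} is missing mandatory column {col!r}"
            )
    return df


def _valid_dates(raw: pd.Series) -> pd.Series:
    """8-digit YYYYMMDD with plausible month/day, else 0 (missing)."""
    v = pd.to_numeric(raw.str.strip(), errors="coerce").fillna(0).astype(np.int64)
    month = (v // 100) % 100
    day = v % 100
    ok = (v >= 10000101) & (v <= 99991231) & (month >= 1) & (month <= 12) & (day >= 1) & (day <= 31)
    n_bad = int(((v != 0) & ~ok).sum())
    if n_bad:
        logger.warning("%d unparseable fda_dt values set to 0", n_bad)
    return v.where(ok, 0)


def _age_groups(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    yrs = pd.to_numeric(age.str.strip(), errors="coerce")
    unit = age_cod.str.strip().str.upper().map(_AGE_UNIT_TO_YEARS)
    # Blank unit with a numeric age defaults to years, as in the FAERS files.
    unit = unit.where(~(unit.isna() & yrs.notna() & (age_cod.str.strip() == "")), 1.0)
    yrs = yrs * unit
    out = pd.Series("unknown", index=age.index, dtype=object)
    out[yrs < 18] = "<18"
    out[(yrs >= 18) & (yrs < 65)] = "18-64"
    out[(yrs >= 65) & (yrs <= 85)] = "65-85"
    out[yrs > 85] = ">85"
    return out


def _sanitize(s: pd.Series) -> pd.Series:
    """Strip and remove the two delimiter characters from free-text fields."""
    return s.str.strip().str.replace("|", "/", regex=False).str.replace("$", "", regex=False)


def _agg_join(df: pd.DataFrame, col: str, unique: bool = True) -> pd.Series:
    """Pipe-join a column per primaryid (sorted unique values if ``unique``)."""
    vals = df[df[col] != ""]
    if unique:
        return vals.groupby("primaryid")[col].agg(lambda s: "|".join(sorted(set(s))))
    return vals.groupby("primaryid")[col].agg("|".join)


def parse_quarter_tables(paths: Mapping[str, object]) -> pd.DataFrame:
    """Parse one quarter's tables into a cohort frame (one row per DEMO row).

    Parameters
    ----------
    paths
        Mapping from lower-case table name (``demo``, ``drug``, ``reac``,
        optionally ``outc``/``rpsr``/``ther``/``indi``) to file path.  DEMO,
        DRUG and REAC are required; a DEMO row without at least one joined
        drug row and one reaction term is dropped (and counted in the log).

    Returns
    -------
    pandas.DataFrame
        Cohort frame with pipe-joined list fields.  ``drugs_norm`` and
        ``is_target_event`` are placeholders until :func:`standardize_terms`.
    """
    paths = {str(k).lower(): v for k, v in paths.items()}
    for required in ("demo", "drug", "reac"):
        if required not in paths:
            raise FaersFormatError(f"missing required table file: {required.upper()}")

    demo = _read_table(paths["demo"], "demo")
    demo["primaryid"] = pd.to_numeric(demo["primaryid"].str.strip(), errors="coerce")
    demo["caseid"] = pd.to_numeric(demo["caseid"].str.strip(), errors="coerce")
    n_badid = int(demo["primaryid"].isna().sum() + demo["caseid"].isna().sum())
    if n_badid:
        logger.warning("%d DEMO rows with non-numeric primaryid/caseid dropped", n_badid)
    demo = demo.dropna(subset=["primaryid", "caseid"]).copy()
    demo["primaryid"] = demo["primaryid"].astype(np.int64)
    demo["caseid"] = demo["caseid"].astype(np.int64)
    demo["fda_dt"] = _valid_dates(demo["fda_dt"]) if len(demo) else pd.Series([], dtype=np.int64)

    for opt, default in (("age", ""), ("age_cod", ""), ("sex", ""), ("occp_cod", ""), ("reporter_country", "")):
        if opt not in demo.columns:
            demo[opt] = default

    demo["age_group"] = _age_groups(demo["age"], demo["age_cod"])
    sex = demo["sex"].str.strip().str.upper()
    demo["sex_group"] = sex.where(sex.isin(["M", "F"]), "unknown")
    demo["reporter"] = (
        demo["occp_cod"].str.strip().str.upper().map(OCCUPATION_CODES).fillna("unknown")
    )
    country = demo["reporter_country"].str.strip().str.lower()
    demo["country"] = country.where(country != "", "unknown")

    drug = _read_table(paths["drug"], "drug")
    drug["primaryid"] = pd.to_numeric(drug["primaryid"].str.strip(), errors="coerce")
    drug = drug.dropna(subset=["primaryid"])
    drug["primaryid"] = drug["primaryid"].astype(np.int64)
    drug["drugname"] = _sanitize(drug["drugname"])
    role = (
        drug["role_cod"].str.strip().str.upper()
        if "role_cod" in drug.columns
        else pd.Series("", index=drug.index)
    )
    drug["role"] = role.where(role.isin(ROLE_CODES), "unknown")
    if "drug_seq" in drug.columns:
        drug["_seq"] = pd.to_numeric(drug["drug_seq"], errors="coerce").fillna(0)
        drug = drug.sort_values(["primaryid", "_seq"], kind="stable")
    drug = drug[drug["drugname"] != ""]
    drugs_raw = drug.groupby("primaryid")["drugname"].agg("|".join)
    drug_roles = drug.groupby("primaryid")["role"].agg("|".join)

    reac = _read_table(paths["reac"], "reac")
    reac["primaryid"] = pd.to_numeric(reac["primaryid"].str.strip(), errors="coerce")
    reac = reac.dropna(subset=["primaryid"])
    reac["primaryid"] = reac["primaryid"].astype(np.int64)
    reac["pt"] = _sanitize(reac["pt"])
    reactions = _agg_join(reac, "pt")

    cohort = demo.set_index("primaryid")
    cohort["drugs_raw"] = drugs_raw
    cohort["drug_roles"] = drug_roles
    cohort["reactions"] = reactions

    n_demo = len(cohort)
    cohort = cohort.dropna(subset=["drugs_raw", "reactions"])
    dropped = n_demo - len(cohort)
    if dropped:
        logger.info("%d DEMO rows without joined DRUG and REAC rows dropped", dropped)

    # Optional tables attach as extra pipe-joined columns.
    def _optional(name: str, col: str, mapper=None) -> pd.Series:
        if name not in paths:
            return pd.Series("", index=cohort.index, dtype=object)
        tbl = _read_table(paths[name], name)
        tbl["primaryid"] = pd.to_numeric(tbl["primaryid"].str.strip(), errors="coerce")
        tbl = tbl.dropna(subset=["primaryid"])
        tbl["primaryid"] = tbl["primaryid"].astype(np.int64)
        if col not in tbl.columns:
            return pd.Series("", index=cohort.index, dtype=object)
        vals = tbl[col].str.strip().str.upper() if mapper else _sanitize(tbl[col])
        tbl[col] = vals.map(mapper).fillna("unknown") if mapper else vals
        joined = _agg_join(tbl, col)
        return joined.reindex(cohort.index).fillna("")

    cohort["outcomes"] = _optional("outc", "outc_cod", OUTCOME_CODES)
    cohort["report_sources"] = _optional("rpsr", "rpsr_cod")
    cohort["indications"] = _optional("indi", "indi_pt")
    if "ther" in paths:
        ther = _read_table(paths["ther"], "ther")
        ther["primaryid"] = pd.to_numeric(ther["primaryid"].str.strip(), errors="coerce")
        ther = ther.dropna(subset=["primaryid"])
        ther["primaryid"] = ther["primaryid"].astype(np.int64)
        start = ther["start_dt"].str.strip() if "start_dt" in ther.columns else ""
        end = ther["end_dt"].str.strip() if "end_dt" in ther.columns else ""
        ther["span"] = (start + ":" + end) if isinstance(start, pd.Series) else ""
        ther = ther[ther["span"].str.strip(":") != ""]
        cohort["therapy_dates"] = _agg_join(ther, "span").reindex(cohort.index).fillna("")
    else:
        cohort["therapy_dates"] = ""

    cohort = cohort.reset_index()
    cohort["sex"] = cohort["sex_group"]
    cohort["year"] = np.where(cohort["fda_dt"] > 0, cohort["fda_dt"] // 10000, 0)
    cohort["drugs_norm"] = ""
    cohort["is_target_event"] = False
    return cohort[COHORT_COLUMNS].reset_index(drop=True)


# --------------------------------------------------------------------------
# Deduplication


def deduplicate_reports(cohort: pd.DataFrame) -> pd.DataFrame:
    """Collapse case versions: keep max fda_dt per caseid, ties to max primaryid.

    Missing receipt dates are stored as 0, so any dated version beats an
    undated one.  The selection rule is a total order per caseid, which makes
    the operation idempotent and independent of input row order.
    """
    kept = (
        cohort.sort_values(["caseid", "fda_dt", "primaryid"], kind="stable")
        .groupby("caseid", as_index=False, sort=False)
        .tail(1)
    )
    out = kept.sort_values("primaryid", kind="stable").reset_index(drop=True)
    logger.info("deduplicated %d rows to %d cases", len(cohort), len(out))
    return out


# --------------------------------------------------------------------------
# Standardization


def standardize_terms(cohort: pd.DataFrame, term_map: TermMap) -> pd.DataFrame:
    """Map verbatim drug names to ingredients and flag target-event reports.

    Unmapped drug names are retained under their lowercased raw string rather
    than dropped (dropping would bias the non-event cells of every table);
    the count of unmapped name occurrences is logged and stored in
    ``cohort.attrs['n_unmapped_drugs']``.
    """
    if not term_map.event_terms:
        raise ValueError("event_terms is empty: no target-event definition")

    cache: dict[str, str] = {}
    n_unmapped = 0

    def _norm_one(raw: str) -> str:
        hit = cache.get(raw)
        if hit is None:
            mapped = term_map.normalize_drug(raw)
            hit = cache[raw] = mapped if mapped else raw.strip().lower()
        return hit

    drugs_norm = []
    unmapped_flags = term_map.drug_synonyms
    for joined in cohort["drugs_raw"]:
        names = joined.split("|")
        drugs_norm.append("|".join(_norm_one(r) for r in names))
        n_unmapped += sum(1 for r in names if _key(r) not in unmapped_flags)

    events = term_map.event_terms
    is_target = [
        any(_key(t) in events for t in joined.split("|"))
        for joined in cohort["reactions"]
    ]

    out = cohort.copy()
    out["drugs_norm"] = drugs_norm
    out["is_target_event"] = is_target
    out.attrs["n_unmapped_drugs"] = n_unmapped
    if n_unmapped:
        logger.info("%d drug-name occurrences had no synonym entry", n_unmapped)
    return out


# --------------------------------------------------------------------------
# Flat-file round trip and record view

_BOOL = {"True": True, "False": False, "1": True, "0": False}


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort to a tab-separated flat file (one row per report)."""
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("primaryid", "caseid", "fda_dt", "year"):
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
    df["is_target_event"] = df["is_target_event"].map(_BOOL).astype(bool)
    return df[COHORT_COLUMNS]


def frame_to_reports(cohort: pd.DataFrame) -> list:
    """Typed record view of a cohort frame as AdverseEventReport objects."""
    reports = []
    for row in cohort.itertuples(index=False):
        raws = row.drugs_raw.split("|") if row.drugs_raw else []
        roles = row.drug_roles.split("|") if row.drug_roles else []
        norms = row.drugs_norm.split("|") if row.drugs_norm else [""] * len(raws)
        drugs = [
            DrugRow(raw_name=r, normalized_name=n, role=q)
            for r, n, q in zip(raws, norms, roles)
        ]
        reports.append(
            AdverseEventReport(
                primaryid=int(row.primaryid),
                caseid=int(row.caseid),
                fda_dt=int(row.fda_dt),
                age_group=row.age_group,
                sex=row.sex,
                reporter=row.reporter,
                country=row.country,
                outcomes=frozenset(row.outcomes.split("|")) - {""},
                drugs=drugs,
                reactions=frozenset(row.reactions.split("|")) - {""},
                is_target_event=bool(row.is_target_event),
            )
        )
    return reports
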