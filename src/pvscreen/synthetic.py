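"""Seeded generator of FAERS-dialect quarterly files with known ground truth.

The generator emulates a spontaneous-reporting cohort: each report draws a
set of drugs from a catalog (verbatim names drawn from per-drug synonym
lists, so name standardization is exercised), demographics from configurable
categorical distributions whose defaults mimic the published ED cohort's
shares, and a target adverse event whose odds are the baseline odds
multiplied by the implanted odds ratio theta of every implanted drug on the
report.  Implanting on the odds scale makes theta the asymptotic estimand of
the reporting odds ratio, so parameter recovery is a clean end-to-end check.

A configurable fraction of cases is additionally emitted in two or three
versions (same CASEID, strictly later receipt date and/or higher PRIMARYID)
together with a manifest naming the version the deduplication rule must
keep.

Everything is driven by one global seed; each stage draws from its own
named substream, so adding a stage never shifts the draws of another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import yaml

from ._util import substream
from .faers_io import (
    COHORT_COLUMNS,
    OCCUPATION_TO_CODE,
    OUTCOME_TO_CODE,
    TermMap,
)

logger = logging.getLogger("pvscreen.synthetic")

__all__ = [
    "DrugSpec",
    "SyntheticCohortConfig",
    "DEFAULT_CATALOG",
    "null_catalog",
    "single_signal_config",
    "generate_reports",
    "implant_duplicates",
    "write_quarter_files",
    "term_map_for",
    "write_term_files",
]


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug: ingredient, marginal use probability, synonyms, theta.

    ``theta`` is the implanted odds multiplier for the target event
    (theta = 1 means the drug is null).
    """

    ingredient: str
    use_probability: float
    synonyms: Tuple[str, ...] = ()
    theta: float = 1.0


#: Catalog mimicking the published ED screen: the implanted odds ratios are the
#: reported RORs of the flagged drugs, plus a handful of null comparators; use
#: probabilities are scaled so the statin a-cells at n = 200,000 give interval
#: widths comparable to the published ones.
DEFAULT_CATALOG: Tuple[DrugSpec, ...] = (
    DrugSpec("finasteride", 0.010, ("PROPECIA", "PROSCAR", "FINASTERIDE"), 55.73),
    DrugSpec("vardenafil", 0.003, ("LEVITRA", "VARDENAFIL HCL"), 164.27),
    DrugSpec("dutasteride", 0.003, ("AVODART",), 19.51),
    DrugSpec("tamsulosin", 0.008, ("FLOMAX", "TAMSULOSIN HCL"), 8.26),
    DrugSpec("tadalafil", 0.008, ("CIALIS",), 8.13),
    DrugSpec("atorvastatin", 0.025, ("LIPITOR", "ATORVASTATIN CALCIUM"), 3.36),
    DrugSpec("rosuvastatin", 0.015, ("CRESTOR", "ROSUVASTATIN CALCIUM"), 3.22),
    DrugSpec("metformin", 0.050, ("GLUCOPHAGE", "METFORMIN HCL"), 1.0),
    DrugSpec("lisinopril", 0.040, ("PRINIVIL", "ZESTRIL"), 1.0),
    DrugSpec("omeprazole", 0.040, ("PRILOSEC",), 1.0),
    DrugSpec("sertraline", 0.030, ("ZOLOFT",), 1.0),
    DrugSpec("amlodipine", 0.040, ("NORVASC",), 1.0),
    DrugSpec("ibuprofen", 0.060, ("ADVIL", "MOTRIN"), 1.0),
)

DEFAULT_BACKGROUND_TERMS: Tuple[str, ...] = (
    "Nausea", "Headache", "Dizziness", "Fatigue", "Rash", "Myalgia",
    "Insomnia", "Diarrhoea", "Dyspnoea", "Arthralgia", "Pruritus", "Vomiting",
)

#: Demographic shares shaped like the published ED cohort (49.4% aged 18-64,
#: 52.0% consumer-reported, 35.6% other-serious outcome, US-dominated country
#: mix, reporting peak in 2015).
DEFAULT_DEMOGRAPHICS: Dict[str, Dict[str, float]] = {
    "age_group": {"<18": 0.020, "18-64": 0.494, "65-85": 0.250, ">85": 0.030, "unknown": 0.206},
    "sex": {"M": 0.880, "F": 0.070, "unknown": 0.050},
    "reporter": {
        "consumer": 0.520, "physician": 0.211, "pharmacist": 0.060,
        "other-health-professional": 0.090, "lawyer": 0.010, "unknown": 0.109,
    },
    "outcome": {
        "other-serious": 0.356, "disability": 0.090, "hospitalization": 0.120,
        "death": 0.025, "life-threatening": 0.015, "congenital-anomaly": 0.002,
        "unknown": 0.392,
    },
    "country": {
        "us": 0.517, "gb": 0.101, "de": 0.048, "fr": 0.032, "ca": 0.025,
        "other": 0.182, "unknown": 0.095,
    },
}

DEFAULT_YEAR_WEIGHTS: Dict[int, float] = {
    2004: 0.020, 2005: 0.022, 2006: 0.024, 2007: 0.026, 2008: 0.028,
    2009: 0.030, 2010: 0.033, 2011: 0.036, 2012: 0.042, 2013: 0.052,
    2014: 0.065, 2015: 0.079, 2016: 0.062, 2017: 0.058, 2018: 0.056,
    2019: 0.060, 2020: 0.070, 2021: 0.055, 2022: 0.050, 2023: 0.047,
    2024: 0.045, 2025: 0.040,
}


def null_catalog(
    n_drugs: int = 100, use_probability: float = 0.03, theta: float = 1.0
) -> Tuple[DrugSpec, ...]:
    """A catalog of generic, exchangeable drugs (for null / power studies)."""
    return tuple(
        DrugSpec(f"drug{i:03d}", use_probability, (f"DRUG{i:03d}",), theta)
        for i in range(1, n_drugs + 1)
    )


def single_signal_config(
    ingredient: str,
    theta: float,
    use_probability: float = 0.06,
    synonyms: Tuple[str, ...] = (),
    n_reports: int = 200_000,
    baseline_event_prob: float = 0.03,
    n_null_drugs: int = 8,
    null_use_probability: float = 0.04,
    seed: int = 0,
) -> "SyntheticCohortConfig":
    """A cohort with exactly one implanted signal among null comparators.

    With a single implanted drug the implanted theta is exactly the ROR
    estimand (no background contamination from other signals), which makes
    this the configuration of choice for effect-recovery studies.

    Because every report is guaranteed at least one drug (empty draws are
    redrawn), realized exposure shares exceed the nominal use probabilities
    by the factor 1 / P(any drug drawn); with dense null comparators that
    factor stays close to 1 and the target drug's realized share is
    approximately ``use_probability / (1 - prod(1 - p_j))``.
    """
    drugs = null_catalog(n_null_drugs, null_use_probability) + (
        DrugSpec(ingredient, use_probability, synonyms, theta),
    )
    return SyntheticCohortConfig(
        n_reports=n_reports,
        drugs=drugs,
        baseline_event_prob=baseline_event_prob,
        seed=seed,
    )


@dataclass
class SyntheticCohortConfig:
    """All the knobs of the generator; fully determines the output with seed."""

    n_reports: int = 20000
    drugs: Tuple[DrugSpec, ...] = DEFAULT_CATALOG
    baseline_event_prob: float = 0.025
    event_term: str = "Erectile dysfunction"
    background_terms: Tuple[str, ...] = DEFAULT_BACKGROUND_TERMS
    demographics: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    )
    year_weights: Dict[int, float] = field(default_factory=lambda: dict(DEFAULT_YEAR_WEIGHTS))
    duplicate_rate: float = 0.0
    seed: int = 0

    @property
    def implanted_signals(self) -> Dict[str, float]:
        return {d.ingredient: d.theta for d in self.drugs if d.theta != 1.0}

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not 0.0 < self.baseline_event_prob < 1.0:
            raise ValueError("baseline_event_prob must lie in (0, 1)")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        if not any(d.use_probability > 0 for d in self.drugs):
            raise ValueError("no catalog drug has positive use probability")
        for d in self.drugs:
            if not 0.0 <= d.use_probability <= 1.0:
                raise ValueError(f"{d.ingredient}: use_probability outside [0, 1]")
            if d.theta < 0:
                raise ValueError(f"{d.ingredient}: theta must be >= 0")
        for name, dist in list(self.demographics.items()) + [
            ("year", {str(k): v for k, v in self.year_weights.items()})
        ]:
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} distribution sums to {total}, not 1")
            if any(p < 0 or p > 1 for p in dist.values()):
                raise ValueError(f"{name} distribution has probabilities outside [0, 1]")

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticCohortConfig":
        raw = dict(raw)
        if "drugs" in raw:
            raw["drugs"] = tuple(
                DrugSpec(
                    ingredient=str(d["ingredient"]),
                    use_probability=float(d["use_probability"]),
                    synonyms=tuple(d.get("synonyms", ())),
                    theta=float(d.get("theta", 1.0)),
                )
                for d in raw["drugs"]
            )
        for key in ("background_terms",):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "year_weights" in raw:
            raw["year_weights"] = {int(k): float(v) for k, v in raw["year_weights"].items()}
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


# --------------------------------------------------------------------------
# Report generation


def _draw_categorical(rng: np.random.Generator, dist: Dict[str, float], n: int) -> np.ndarray:
    levels = list(dist.keys())
    probs = np.array([dist[k] for k in levels], dtype=float)
    return rng.choice(np.array(levels, dtype=object), size=n, p=probs / probs.sum())


def generate_reports(config: SyntheticCohortConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the pre-duplication cohort plus its ground-truth signal table.

    Returns ``(cohort, truth)`` where the cohort frame carries the
    generator's own normalized drug names and target-event flags (the
    ground truth a parser + standardizer must reproduce), and ``truth``
    lists each catalog drug's implanted theta.
    """
    config.validate()
    n = config.n_reports
    drugs = config.drugs
    n_drugs = len(drugs)
    probs = np.array([d.use_probability for d in drugs])

    rng = substream(config.seed, "reports")

    # Drug exposure matrix; redraw rows with no drug at all.
    used = rng.random((n, n_drugs)) < probs
    empty = ~used.any(axis=1)
    while empty.any():
        used[empty] = rng.random((int(empty.sum()), n_drugs)) < probs
        empty = ~used.any(axis=1)

    # Target event: baseline odds times the product of implanted thetas.
    log_theta = np.log(np.array([d.theta for d in drugs], dtype=float))
    p0 = config.baseline_event_prob
    odds = (p0 / (1.0 - p0)) * np.exp(used @ log_theta)
    event = rng.random(n) < odds / (1.0 + odds)

    # Demographics.
    demo = {
        cat: _draw_categorical(rng, dist, n) for cat, dist in config.demographics.items()
    }
    years = _draw_categorical(
        rng, {str(k): v for k, v in config.year_weights.items()}, n
    ).astype(int)
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)
    fda_dt = years * 10000 + months * 100 + days

    # Reactions: the target term on event reports, plus background noise.
    bg = np.array(config.background_terms, dtype=object)
    n_bg_event = rng.integers(0, 3, size=n)  # 0-2 extra terms on event reports
    n_bg_other = rng.integers(1, 4, size=n)  # 1-3 terms on non-event reports
    n_bg = np.where(event, n_bg_event, n_bg_other)
    pick = np.argsort(rng.random((n, len(bg))), axis=1)

    # Verbatim drug names: one synonym per mention.
    syn_arrays = [
        np.array(d.synonyms if d.synonyms else (d.ingredient.upper(),), dtype=object)
        for d in drugs
    ]
    syn_choice = [
        arr[rng.integers(0, len(arr), size=n)] for arr in syn_arrays
    ]
    ingredient_names = [d.ingredient for d in drugs]

    drugs_raw, drug_roles, drugs_norm, reactions = [], [], [], []
    for i in range(n):
        cols = np.flatnonzero(used[i])
        drugs_raw.append("|".join(syn_choice[j][i] for j in cols))
        drug_roles.append("|".join("PS" if k == 0 else "SS" for k in range(len(cols))))
        drugs_norm.append("|".join(ingredient_names[j] for j in cols))
        terms = {bg[k] for k in pick[i, : n_bg[i]]}
        if event[i]:
            terms.add(config.event_term)
        reactions.append("|".join(sorted(terms)))

    outcomes = np.where(
        demo["outcome"] == "unknown", "", demo["outcome"]
    )

    cohort = pd.DataFrame(
        {
            "primaryid": 100_000_000 + 10 * np.arange(n, dtype=np.int64),
            "caseid": 60_000_000 + np.arange(n, dtype=np.int64),
            "fda_dt": fda_dt.astype(np.int64),
            "age_group": demo["age_group"],
            "sex": demo["sex"],
            "reporter": demo["reporter"],
            "country": demo["country"],
            "year": years.astype(np.int64),
            "outcomes": outcomes,
            "drugs_raw": drugs_raw,
            "drug_roles": drug_roles,
            "drugs_norm": drugs_norm,
            "reactions": reactions,
            "is_target_event": event,
            "report_sources": "",
            "therapy_dates": "",
            "indications": "",
        }
    )[COHORT_COLUMNS]

    truth = pd.DataFrame(
        {
            "ingredient": ingredient_names,
            "theta": [d.theta for d in drugs],
            "use_probability": [d.use_probability for d in drugs],
        }
    )
    logger.info(
        "generated %d reports, %d target-event reports (%.2f%%)",
        n, int(event.sum()), 100.0 * event.mean(),
    )
    return cohort, truth


# --------------------------------------------------------------------------
# Duplicate implantation


def implant_duplicates(
    cohort: pd.DataFrame, config: SyntheticCohortConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Emit extra versions of a fraction of cases, plus the survivor manifest.

    Each selected case gains one or two extra versions sharing its caseid
    with a strictly later receipt date (70% of versions) or the same date
    and a higher primaryid (30%).  The manifest lists, per case, the
    primaryid that the dedup rule (max fda_dt, then max primaryid) must
    keep.  Row order of the output is shuffled so downstream order
    independence is exercised.
    """
    rate = config.duplicate_rate
    if not 0.0 <= rate < 1.0:
        raise ValueError("duplicate_rate must lie in [0, 1)")
    rng = substream(config.seed, "duplicates")
    if rate == 0.0 or cohort.empty:
        manifest = pd.DataFrame(
            {"caseid": cohort["caseid"], "keep_primaryid": cohort["primaryid"]}
        )
        return cohort.copy(), manifest

    n_cases = len(cohort)
    n_dup = int(round(rate * n_cases))
    chosen = rng.choice(n_cases, size=n_dup, replace=False)

    extra_rows = []
    for pos in chosen:
        base = cohort.iloc[pos]
        n_versions = int(rng.integers(1, 3))
        fda = int(base["fda_dt"])
        for v in range(1, n_versions + 1):
            row = base.copy()
            row["primaryid"] = int(base["primaryid"]) + v
            if rng.random() < 0.7 or fda == 0:
                stamp = pd.Timestamp(str(fda if fda else 20150101)) + pd.Timedelta(
                    days=int(rng.integers(30, 400)) * v
                )
                fda = int(stamp.strftime("%Y%m%d"))
            row["fda_dt"] = fda
            extra_rows.append(row)

    combined = pd.concat([cohort, pd.DataFrame(extra_rows)], ignore_index=True)
    order = rng.permutation(len(combined))
    combined = combined.iloc[order].reset_index(drop=True)

    survivors = (
        combined.sort_values(["caseid", "fda_dt", "primaryid"], kind="stable")
        .groupby("caseid", as_index=False)
        .tail(1)
    )
    manifest = (
        survivors[["caseid", "primaryid"]]
        .rename(columns={"primaryid": "keep_primaryid"})
        .sort_values("caseid")
        .reset_index(drop=True)
    )
    logger.info("implanted duplicates for %d of %d cases", n_dup, n_cases)
    return combined, manifest


# --------------------------------------------------------------------------
# FAERS-dialect writer

_AGE_REPRESENTATIVE = {"<18": 12, "18-64": 45, "65-85": 72, ">85": 88}


def _age_fields(age_group: str, primaryid: int) -> Tuple[str, str]:
    """Numeric age + unit for a group, cycling through YR/DEC/MON encodings."""
    years = _AGE_REPRESENTATIVE.get(age_group)
    if years is None:
        return "", ""
    if primaryid % 7 == 0:
        return (f"{years / 10:g}", "DEC")
    if primaryid % 11 == 0:
        return (str(years * 12), "MON")
    return (str(years), "YR")


def write_quarter_files(cohort: pd.DataFrame, out_dir) -> Dict[str, Path]:
    """Write DEMO/DRUG/REAC/OUTC quarter files parseable by faers_io.

    Drug rows carry the verbatim synonyms (never the normalized names), so
    the reader's standardization step is genuinely exercised.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ages, age_cods = zip(*(
        _age_fields(g, int(p)) for g, p in zip(cohort["age_group"], cohort["primaryid"])
    )) if len(cohort) else ((), ())
    demo = pd.DataFrame(
        {
            "primaryid": cohort["primaryid"],
            "caseid": cohort["caseid"],
            "fda_dt": cohort["fda_dt"].where(cohort["fda_dt"] != 0, ""),
            "age": ages if len(cohort) else [],
            "age_cod": age_cods if len(cohort) else [],
            "sex": cohort["sex"].where(cohort["sex"] != "unknown", ""),
            "occp_cod": cohort["reporter"].map(OCCUPATION_TO_CODE).fillna(""),
            "reporter_country": cohort["country"].where(cohort["country"] != "unknown", ""),
        }
    )

    drug_rows = []
    for pid, cid, raws, roles in zip(
        cohort["primaryid"], cohort["caseid"], cohort["drugs_raw"], cohort["drug_roles"]
    ):
        for seq, (raw, role) in enumerate(zip(raws.split("|"), roles.split("|")), start=1):
            drug_rows.append((pid, cid, seq, role, raw))
    drug = pd.DataFrame(
        drug_rows, columns=["primaryid", "caseid", "drug_seq", "role_cod", "drugname"]
    )

    reac_rows = [
        (pid, cid, term)
        for pid, cid, joined in zip(cohort["primaryid"], cohort["caseid"], cohort["reactions"])
        for term in joined.split("|")
        if term
    ]
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "caseid", "pt"])

    outc_rows = [
        (pid, cid, OUTCOME_TO_CODE[o])
        for pid, cid, joined in zip(cohort["primaryid"], cohort["caseid"], cohort["outcomes"])
        for o in joined.split("|")
        if o
    ]
    outc = pd.DataFrame(outc_rows, columns=["primaryid", "caseid", "outc_cod"])

    paths = {}
    for name, frame in (("demo", demo), ("drug", drug), ("reac", reac), ("outc", outc)):
        path = out_dir / f"{name.upper()}.txt"
        frame.to_csv(path, sep="$", index=False)
        paths[name] = path
    return paths


# --------------------------------------------------------------------------
# Term files


def term_map_for(config: SyntheticCohortConfig) -> TermMap:
    """The TermMap matching a config's catalog (synonyms plus ingredient)."""
    synonyms = {}
    for d in config.drugs:
        synonyms[d.ingredient] = d.ingredient
        for s in d.synonyms:
            synonyms[s] = d.ingredient
    return TermMap(drug_synonyms=synonyms, event_terms=frozenset([config.event_term]))


def write_term_files(config: SyntheticCohortConfig, synonyms_path, event_terms_path) -> None:
    """Write the TermMap files (raw<TAB>ingredient; one event term per line)."""
    lines = []
    for d in config.drugs:
        lines.append(f"{d.ingredient}\t{d.ingredient}")
        for s in d.synonyms:
            lines.append(f"{s}\t{d.ingredient}")
    Path(synonyms_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    Path(event_terms_path).write_text(config.event_term + "\n", encoding="utf-8")
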