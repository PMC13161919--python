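"""Shared fixtures: hand-built cohorts and tiny quarter files."""

from __future__ import annotations

import pandas as pd
import pytest

from pvscreen.faers_io import COHORT_COLUMNS

_DEFAULT_ROW = {
    "primaryid": 1,
    "caseid": 1,
    "fda_dt": 20200115,
    "age_group": "18-64",
    "sex": "M",
    "reporter": "consumer",
    "country": "us",
    "year": 2020,
    "outcomes": "",
    "drugs_raw": "DRUG A",
    "drug_roles": "PS",
    "drugs_norm": "druga",
    "reactions": "Nausea",
    "is_target_event": False,
    "report_sources": "",
    "therapy_dates": "",
    "indications": "",
}


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Build a standardized cohort frame from partial row dicts."""
    filled = []
    for i, row in enumerate(rows):
        rec = dict(_DEFAULT_ROW)
        rec.update(row)
        if "primaryid" not in row:
            rec["primaryid"] = i + 1
        if "caseid" not in row:
            rec["caseid"] = i + 1
        filled.append(rec)
    df = pd.DataFrame(filled, columns=COHORT_COLUMNS)
    df["is_target_event"] = df["is_target_event"].astype(bool)
    return df


@pytest.fixture
def cohort_builder():
    return make_cohort


def write_quarter(tmp_path, demo_rows, drug_rows, reac_rows, **extra_tables):
    """Write minimal $-delimited quarter files and return the path mapping.

    Each *_rows argument is a list of already-$-joined data lines; headers
    are fixed per table.
    """
    headers = {
        "demo": "primaryid$caseid$fda_dt$age$age_cod$sex$occp_cod$reporter_country",
        "drug": "primaryid$caseid$drug_seq$role_cod$drugname",
        "reac": "primaryid$caseid$pt",
        "outc": "primaryid$caseid$outc_cod",
        "rpsr": "primaryid$caseid$rpsr_cod",
        "ther": "primaryid$caseid$dsg_drug_seq$start_dt$end_dt",
        "indi": "primaryid$caseid$indi_drug_seq$indi_pt",
    }
    tables = {"demo": demo_rows, "drug": drug_rows, "reac": reac_rows, **extra_tables}
    paths = {}
    for name, rows in tables.items():
        path = tmp_path / f"{name.upper()}.txt"
        path.write_text("\n".join([headers[name]] + list(rows)) + "\n", encoding="utf-8")
        paths[name] = path
    return paths


@pytest.fixture
def quarter_writer():
    return write_quarter
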