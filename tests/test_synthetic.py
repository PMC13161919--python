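"""Generator ground truth: determinism, duplicates, round trips, power."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from pvscreen.contingency import build_all_pairs, build_contingency
from pvscreen.dispro import compute_signals
from pvscreen.faers_io import deduplicate_reports, parse_quarter_tables, standardize_terms
from pvscreen.synthetic import (
    DrugSpec,
    SyntheticCohortConfig,
    generate_reports,
    implant_duplicates,
    null_catalog,
    term_map_for,
    write_quarter_files,
    write_term_files,
)

CONTENT_COLUMNS = [
    "caseid", "age_group", "sex", "reporter", "country", "outcomes",
    "drugs_raw", "drug_roles", "drugs_norm", "reactions", "is_target_event",
]


def small_config(**kw) -> SyntheticCohortConfig:
    defaults = dict(n_reports=1000, drugs=null_catalog(8, 0.1), seed=42)
    defaults.update(kw)
    return SyntheticCohortConfig(**defaults)


class TestGenerateReports:
    def test_same_seed_gives_byte_identical_quarter_files(self, tmp_path):
        for run in ("one", "two"):
            cohort, _ = generate_reports(small_config())
            write_quarter_files(cohort, tmp_path / run)
        for name in ("DEMO", "DRUG", "REAC", "OUTC"):
            assert (tmp_path / "one" / f"{name}.txt").read_bytes() == (
                tmp_path / "two" / f"{name}.txt"
            ).read_bytes()

    def test_different_seeds_differ(self):
        c1, _ = generate_reports(small_config(seed=1))
        c2, _ = generate_reports(small_config(seed=2))
        assert not c1.equals(c2)

    def test_every_report_has_a_drug_and_a_reaction(self):
        cohort, _ = generate_reports(small_config())
        assert (cohort["drugs_raw"] != "").all()
        assert (cohort["reactions"] != "").all()

    def test_realized_event_rate_tracks_configured_marginal(self):
        cfg = SyntheticCohortConfig(
            n_reports=100_000, drugs=null_catalog(10, 0.05),
            baseline_event_prob=0.03, seed=8,
        )
        cohort, _ = generate_reports(cfg)
        rate = cohort["is_target_event"].mean()
        assert abs(rate - 0.03) / 0.03 < 0.10

    def test_implanted_theta_is_ror_estimand(self):
        # theta = 4 implanted for one drug: pipeline ROR within 3 SE of 4
        drugs = null_catalog(6, 0.04) + (DrugSpec("target", 0.05, ("TARGET",), 4.0),)
        cfg = SyntheticCohortConfig(
            n_reports=200_000, drugs=drugs, baseline_event_prob=0.01, seed=17
        )
        cohort, truth = generate_reports(cfg)
        assert truth.set_index("ingredient").loc["target", "theta"] == 4.0
        t = build_contingency(cohort, "target")
        ror = (t.a * t.d) / (t.b * t.c)
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        assert abs(math.log(ror) - math.log(4.0)) < 3 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_reports"):
            generate_reports(small_config(n_reports=0))
        with pytest.raises(ValueError, match="positive use"):
            generate_reports(small_config(drugs=(DrugSpec("x", 0.0),)))
        with pytest.raises(ValueError, match="sums"):
            cfg = small_config()
            cfg.demographics["sex"] = {"M": 0.5, "F": 0.2, "unknown": 0.2}
            generate_reports(cfg)


class TestImplantDuplicates:
    def test_zero_rate_is_identity(self):
        cohort, _ = generate_reports(small_config())
        out, manifest = implant_duplicates(cohort, small_config(duplicate_rate=0.0))
        pd.testing.assert_frame_equal(out, cohort)
        assert set(manifest["keep_primaryid"]) == set(cohort["primaryid"])

    def test_dedup_recovers_exactly_the_manifest_survivors(self):
        cfg = small_config(duplicate_rate=0.1)
        cohort, _ = generate_reports(cfg)
        with_dups, manifest = implant_duplicates(cohort, cfg)
        assert len(with_dups) > len(cohort)
        deduped = deduplicate_reports(with_dups)
        assert len(deduped) == len(cohort)
        assert set(deduped["primaryid"]) == set(manifest["keep_primaryid"])

    def test_duplicate_versions_share_caseid_and_never_precede_original(self):
        cfg = small_config(duplicate_rate=0.2)
        cohort, _ = generate_reports(cfg)
        with_dups, _ = implant_duplicates(cohort, cfg)
        base = cohort.set_index("primaryid")
        extras = with_dups[~with_dups["primaryid"].isin(cohort["primaryid"])]
        for row in extras.itertuples(index=False):
            original = cohort[cohort["caseid"] == row.caseid].iloc[0]
            assert (row.fda_dt, row.primaryid) > (
                int(original["fda_dt"]), int(original["primaryid"])
            )


class TestWriteQuarterFiles:
    def test_round_trip_recovers_ground_truth_cohort(self, tmp_path):
        cfg = small_config(duplicate_rate=0.1, drugs=null_catalog(8, 0.1) + (
            DrugSpec("atorvastatin", 0.1, ("LIPITOR", "ATORVASTATIN CALCIUM"), 2.0),
        ))
        cohort, _ = generate_reports(cfg)
        with_dups, _ = implant_duplicates(cohort, cfg)
        paths = write_quarter_files(with_dups, tmp_path)
        parsed = parse_quarter_tables(paths)
        deduped = deduplicate_reports(parsed)
        standardized = standardize_terms(deduped, term_map_for(cfg))
        got = standardized.sort_values("caseid").reset_index(drop=True)
        want = cohort.sort_values("caseid").reset_index(drop=True)
        pd.testing.assert_frame_equal(got[CONTENT_COLUMNS], want[CONTENT_COLUMNS])

    def test_empty_cohort_writes_header_only_files(self, tmp_path):
        cohort, _ = generate_reports(small_config())
        paths = write_quarter_files(cohort.iloc[0:0], tmp_path)
        for path in paths.values():
            assert len(path.read_text().strip().splitlines()) == 1

    def test_synonyms_appear_verbatim_in_drug_file(self, tmp_path):
        cfg = small_config(drugs=(
            DrugSpec("atorvastatin", 1.0, ("LIPITOR",), 1.0),
        ))
        cohort, _ = generate_reports(cfg)
        paths = write_quarter_files(cohort, tmp_path)
        assert "LIPITOR" in paths["drug"].read_text()
        assert "atorvastatin" not in paths["drug"].read_text()

    def test_term_files_round_trip(self, tmp_path):
        cfg = small_config()
        write_term_files(cfg, tmp_path / "syn.tsv", tmp_path / "events.txt")
        from pvscreen.faers_io import load_term_map

        tm = load_term_map(tmp_path / "syn.tsv", tmp_path / "events.txt")
        assert tm.normalize_drug("DRUG001") == "drug001"
        assert tm.is_target([cfg.event_term])


def empirical_power(theta: float, n: int, replicates: int, seed0: int) -> float:
    """Share of replicates in which the implanted drug passes all criteria."""
    hits = 0
    for r in range(replicates):
        drugs = null_catalog(9, 0.05) + (DrugSpec("target", 0.05, ("TARGET",), theta),)
        cfg = SyntheticCohortConfig(
            n_reports=n, drugs=drugs, baseline_event_prob=0.05, seed=seed0 + r
        )
        cohort, _ = generate_reports(cfg)
        tables = build_all_pairs(cohort)
        results, _ = compute_signals(tables)
        row = results[results["drug"] == "target"]
        hits += int(len(row) > 0 and bool(row["is_signal"].iloc[0]))
    return hits / replicates


def test_power_of_conjunctive_criteria_monotone_in_n_and_theta():
    """Detection power grows with cohort size and implanted effect size."""
    grid_n = [3000, 9000, 27000]
    grid_theta = [1.5, 3.0, 6.0]
    reps = 12
    power = {
        (n, th): empirical_power(th, n, reps, seed0=1000 * i + 100 * j)
        for i, n in enumerate(grid_n)
        for j, th in enumerate(grid_theta)
    }
    slack = 1.0 / reps  # one replicate of sampling noise
    for th in grid_theta:
        for n_small, n_large in zip(grid_n, grid_n[1:]):
            assert power[(n_large, th)] >= power[(n_small, th)] - slack
    for n in grid_n:
        for th_small, th_large in zip(grid_theta, grid_theta[1:]):
            assert power[(n, th_large)] >= power[(n, th_small)] - slack
    assert power[(27000, 6.0)] == 1.0
    assert power[(3000, 1.5)] <= 0.5
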