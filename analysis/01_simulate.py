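"""Generate the synthetic study cohort: FAERS-dialect quarter files with
known ground truth.

The default catalog mirrors the shape of the published ED screen: seven
drugs implanted with the reported odds ratios (finasteride, vardenafil,
dutasteride, tamsulosin, tadalafil, atorvastatin, rosuvastatin) among six
null comparators, demographics drawn from the published cohort shares, and
8% of cases emitted in multiple versions to exercise deduplication.

Writes DEMO/DRUG/REAC/OUTC quarter files, the drug-synonym and event-term
maps, the implanted-signal ground truth and the duplicate-survivor manifest
under results/synthetic/.
"""

import argparse
from pathlib import Path

from pvscreen.synthetic import (
    SyntheticCohortConfig,
    generate_reports,
    implant_duplicates,
    write_quarter_files,
    write_term_files,
)

N_REPORTS = 60_000
DUPLICATE_RATE = 0.08


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results/synthetic"))
    args = parser.parse_args()

    config = SyntheticCohortConfig(
        n_reports=N_REPORTS, duplicate_rate=DUPLICATE_RATE, seed=args.seed
    )
    cohort, truth = generate_reports(config)
    with_dups, manifest = implant_duplicates(cohort, config)

    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    write_quarter_files(with_dups, out)
    write_term_files(config, out / "drug_synonyms.tsv", out / "event_terms.txt")
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    manifest.to_csv(out / "dedup_manifest.tsv", sep="\t", index=False)

    n_events = int(cohort["is_target_event"].sum())
    print(f"simulated {len(cohort)} reports (seed {args.seed}); "
          f"{n_events} target-event reports ({100 * n_events / len(cohort):.1f}%)")
    print(f"{len(with_dups) - len(cohort)} duplicate case versions implanted "
          f"({DUPLICATE_RATE:.0%} of cases)")
    implanted = truth[truth["theta"] != 1.0]
    print(f"implanted signals: "
          + ", ".join(f"{r.ingredient} (theta={r.theta})" for r in implanted.itertuples()))
    print(f"quarter files, term maps, ground truth and manifest -> {out}/")


if __name__ == "__main__":
    main()
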