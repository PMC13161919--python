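"""Parse the quarter files, deduplicate case versions and standardize terms.

Reads the FAERS-dialect tables written by 01_simulate.py, joins them into
one record per report, collapses duplicate CASEID versions to the latest
receipt date (ties to the higher PRIMARYID), maps verbatim drug names to
ingredients and flags target-event reports.  Verifies the dedup result
against the generator's survivor manifest and writes the analysis cohort to
results/cohort.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from pvscreen.faers_io import (
    deduplicate_reports,
    load_term_map,
    parse_quarter_tables,
    standardize_terms,
    write_cohort,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--out", type=Path, default=Path("results/cohort.tsv"))
    args = parser.parse_args()

    paths = {
        name: args.in_dir / f"{name.upper()}.txt"
        for name in ("demo", "drug", "reac", "outc")
        if (args.in_dir / f"{name.upper()}.txt").exists()
    }
    raw = parse_quarter_tables(paths)
    print(f"parsed {len(raw)} report rows from {len(paths)} tables")

    cohort = deduplicate_reports(raw)
    print(f"deduplicated to {len(cohort)} cases "
          f"({len(raw) - len(cohort)} duplicate versions removed)")

    manifest_path = args.in_dir / "dedup_manifest.tsv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path, sep="\t")
        match = set(cohort["primaryid"]) == set(manifest["keep_primaryid"])
        print(f"survivors match the generator manifest: {match}")

    term_map = load_term_map(
        args.in_dir / "drug_synonyms.tsv", args.in_dir / "event_terms.txt"
    )
    cohort = standardize_terms(cohort, term_map)
    n_events = int(cohort["is_target_event"].sum())
    print(f"{n_events} target-event reports "
          f"({100 * n_events / len(cohort):.1f}%); "
          f"{cohort.attrs['n_unmapped_drugs']} unmapped drug-name occurrences")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, args.out)
    print(f"analysis cohort -> {args.out}")


if __name__ == "__main__":
    main()
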