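"""Descriptive demographic summaries of the analysis cohort.

Tabulates age group, sex, reporter occupation, most-serious outcome,
reporter country (known-country denominator) and report year, writing one
table per category under results/.  The synthetic cohort's shares are
drawn to mimic the published ED cohort, so the leading levels should echo
it: 18-64 the dominant age band, consumers the dominant reporters,
other-serious the dominant outcome, 2015 the peak year.
"""

import argparse
from pathlib import Path

from pvscreen.faers_io import read_cohort
from pvscreen.screen import SUPPORTED_CATEGORIES, summarize_demographics


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.tsv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = read_cohort(args.cohort)
    print(f"{len(cohort)} deduplicated reports")
    for category in SUPPORTED_CATEGORIES:
        summary = summarize_demographics(cohort, category)
        path = args.out_dir / f"demography_{category}.tsv"
        summary.to_csv(path, sep="\t", index=False, float_format="%.1f")
        known = summary[summary["level"] != "unknown"]
        lead = known.loc[known["count"].idxmax()]
        print(f"  {category}: leading level {lead['level']!r} "
              f"n={lead['count']} ({lead['pct']}%) -> {path}")


if __name__ == "__main__":
    main()
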