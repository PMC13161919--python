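"""Build one drug-event 2x2 contingency table per normalized drug.

Exposure counts suspect drugs only (primary + secondary suspect roles);
each report counts once per drug however many matching rows it carries.
Writes the per-drug a/b/c/d/N table to results/tables.tsv.
"""

import argparse
from pathlib import Path

from pvscreen.contingency import DEFAULT_ROLE_FILTER, build_all_pairs, write_tables
from pvscreen.faers_io import read_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/tables.tsv"))
    args = parser.parse_args()

    cohort = read_cohort(args.cohort)
    tables = build_all_pairs(cohort, DEFAULT_ROLE_FILTER)
    write_tables(tables, args.out)

    n_event = int(cohort["is_target_event"].sum())
    assert (tables["a"] + tables["b"] + tables["c"] + tables["d"] == tables["N"]).all()
    assert (tables["a"] + tables["c"] == n_event).all()
    print(f"{len(tables)} drug-event tables over {len(cohort)} reports "
          f"({n_event} with the target event)")
    top = tables.head(5)
    print("largest co-report counts: "
          + ", ".join(f"{r.drug} (a={r.a})" for r in top.itertuples()))
    print(f"contingency tables -> {args.out}")


if __name__ == "__main__":
    main()
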