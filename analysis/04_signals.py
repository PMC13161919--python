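"""Compute the four disproportionality statistics and rank the drugs.

Fits the MGPS gamma-mixture prior across all drug-event pairs, computes
ROR (Woolf CI), PRR (Yates chi-squared), BCPNN IC/IC025 and EBGM/EB05 per
drug, applies the conjunctive positive-signal criteria (n >= 3, ROR CI
lower bound > 1, PRR >= 2, chi2 >= 4, IC025 > 0, EB05 > 2), and writes the
full results, the top-30 ranking and the forest-plot table.  Compares each
flagged drug's ROR with the implanted ground truth when available.
"""

import argparse
from pathlib import Path

import pandas as pd

from pvscreen.contingency import read_tables
from pvscreen.dispro import compute_signals, write_results
from pvscreen.screen import forest_table, rank_top_drugs

TOP_K = 30


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--tables", type=Path, default=Path("results/tables.tsv"))
    parser.add_argument("--truth", type=Path, default=Path("results/synthetic/ground_truth.tsv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    tables = read_tables(args.tables)
    results, fit = compute_signals(tables)
    write_results(results, args.out_dir / "signals.tsv")

    p = fit.prior
    print(f"MGPS prior fitted on {len(tables)} pairs: "
          f"alpha1={p.alpha1:.3f} beta1={p.beta1:.3f} "
          f"alpha2={p.alpha2:.3f} beta2={p.beta2:.3f} w={p.w:.3f} "
          f"(loglik {fit.loglik:.1f}, converged={fit.converged})")

    ranked = rank_top_drugs(results, TOP_K)
    ranked.to_csv(args.out_dir / "top_drugs.tsv", sep="\t", index=False,
                  float_format="%.4f")
    forest_table(ranked).to_csv(args.out_dir / "forest.tsv", sep="\t", index=False,
                                float_format="%.4f")
    n_pos = int(ranked["is_signal"].sum())
    print(f"{n_pos} of the top {len(ranked)} drugs meet all positive-signal criteria")

    signals = ranked[ranked["is_signal"]]
    for row in signals.itertuples(index=False):
        print(f"  {row.drug}: n={row.n} ROR={row.ror:.2f} "
              f"({row.ror_lo:.2f}-{row.ror_hi:.2f}) EBGM={row.ebgm:.2f}")

    if args.truth.exists():
        truth = pd.read_csv(args.truth, sep="\t").set_index("ingredient")
        flagged = set(signals["drug"])
        implanted = set(truth.index[truth["theta"] > 1.0])
        print(f"implanted signals recovered: {len(flagged & implanted)}/{len(implanted)}; "
              f"false positives among nulls: {len(flagged - implanted)}")
        print("note: with several signals implanted at once each measured ROR is "
              "attenuated below its implanted theta by the contaminated background")

    print(f"signal tables -> {args.out_dir}/signals.tsv, top_drugs.tsv, forest.tsv")


if __name__ == "__main__":
    main()
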