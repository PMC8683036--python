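#!/usr/bin/env python
"""Corroborate the index against call labels and test species-level effects.

Correlates the per-call index with the binary musical-name label, compares
labelled vs unlabelled calls with the exact rank-sum test, summarizes call
contexts, and runs Welch t-tests of species-maximum index across monogamy,
habitat, arboreality, territoriality and group-size class.
"""

import argparse
from pathlib import Path

import pandas as pd

from ardi import evaluate
from ardi.io import read_metadata, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    index_table = pd.read_csv(args.results_dir / "indices.csv").set_index("vocalization_id")
    metadata = read_metadata(args.data_dir / "metadata.csv")
    species_summary = pd.read_csv(args.results_dir / "species_summary.csv")
    flags = index_table["musical_flag"].astype(bool)

    results = []
    for method in ("pearson_on_ranks", "pearson", "spearman"):
        results.append(
            evaluate.index_label_correlation(index_table["ardi"], flags, method)
        )
    corr = results[0]
    print(f"index vs musical-name label: r = {corr.statistic:.2f} "
          f"(n = {corr.extra['n']}, rank-based)")

    rs = evaluate.ranksum_test(
        index_table.loc[flags, "ardi"], index_table.loc[~flags, "ardi"]
    )
    results.append(rs)
    print(f"rank-sum musical vs other calls: U = {rs.extra['U']:.0f}, "
          f"p = {rs.p_value:.2g} ({rs.extra['method']})")

    battery = evaluate.run_hypothesis_battery(species_summary)
    results.extend(battery)
    for r in battery:
        if r.df is not None:
            print(f"{r.name}: effect {r.effect:+.2f}, t = {r.statistic:.2f}, "
                  f"df = {r.df:.1f}, p = {r.p_value:.3g}")
        else:
            print(f"{r.name}: {r.extra.get('notice', '')}")

    write_table(evaluate.tests_table(results), args.results_dir / "tests.csv")

    cats = evaluate.assign_context_categories(metadata)
    context = evaluate.context_summaries(index_table, cats)
    write_table(context, args.results_dir / "context_summary.csv")
    by_cat = (context[context["metric"] == "ardi"]
              .sort_values("mean", ascending=False))
    print("\nhighest-index call contexts: "
          + ", ".join(f"{r.context_category} ({r.mean:.2f})"
                      for r in by_cat.head(3).itertuples()))


if __name__ == "__main__":
    main()
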