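#!/usr/bin/env python
"""Stage 4 — Friedman feature screen and correlation-matrix PCA.

Reads the stage-3 feature table (or rebuilds it when absent), keeps the
indexes whose distributions differ across the three fatigue states, and
extracts principal components until the cumulative contribution rate
reaches 85%.

Usage: python analysis/04_select_extract.py [--seed N] [--out DIR]
"""

import argparse
from pathlib import Path

import pandas as pd

from fatiguehrv import featstats
from fatiguehrv.pipeline import PipelineConfig, build_feature_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table_path = args.out / "feature_table.csv"
    if table_path.exists():
        table = pd.read_csv(table_path)
    else:
        table = build_feature_table(
            PipelineConfig(signal_level="rr", seed=args.seed))

    sel = featstats.select_features(table)
    sel.report.round(4).to_csv(args.out / "selection_report.csv", index=False)
    print(f"selected {len(sel.selected)} of "
          f"{sel.report['feature'].nunique()} tested indexes")

    pca = featstats.fit_pca(table, features=sel.selected)
    pca.to_json(args.out / "pca_model.json")
    summary = pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(len(pca.eigenvalues))],
        "eigenvalue": pca.eigenvalues.round(4),
        "contribution": pca.contribution.round(4),
        "cumulative": pca.cumulative.round(4),
    })
    summary.to_csv(args.out / "pca_summary.csv", index=False)
    print(f"retained {pca.retained} components "
          f"(cumulative {pca.cumulative[pca.retained - 1]:.3f})")
    print(summary.head(pca.retained + 2).to_string(index=False))


if __name__ == "__main__":
    main()
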