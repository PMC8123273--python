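#!/usr/bin/env python
"""Stage 5 — train the LVQ classifier and the baselines, evaluate held out.

Runs the complete pipeline (simulation, windowing, feature screen, PCA,
classifier training) with held-out participants and prints the test-set
confusion matrix and metric summary for the LVQ model and the neural
network / support-vector baselines.

Usage: python analysis/05_train_evaluate.py [--seed N] [--out DIR]
"""

import argparse
import json
from pathlib import Path

from fatiguehrv.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cfg = PipelineConfig(signal_level="rr", with_baselines=True,
                         seed=args.seed)
    report = run_pipeline(cfg, args.out / "run")

    print(f"config {report.config_hash}: "
          f"{report.n_effective_windows}/{report.n_windows} windows, "
          f"{len(report.selected_features)} features, "
          f"{report.retained_components} components")
    summary = {"lvq": report.evaluation}
    summary.update(report.baseline_evaluations)
    for name, ev in summary.items():
        print(f"{name:>5}: accuracy {ev['accuracy']:.2f}%  "
              f"macro precision {ev['macro_precision']:.2f}%  "
              f"accuracy-variant F1 {ev['f1_accuracy_variant']:.2f}")
    (args.out / "model_comparison.json").write_text(
        json.dumps(summary, indent=2) + "\n")


if __name__ == "__main__":
    main()
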