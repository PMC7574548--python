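"""Assemble the feature table and cross-validate the origin classifier.

Builds 1 kb windows on intergenic OM summits (positives) and OM-free IGR
midpoints (negatives; O-site IGRs held out), scores the 13 features, runs
10x4-fold stratified CV of the RBF SVM per feature subset, ranks features by
F-score, scores the held-out O-site IGRs with the trio classifiers, and
writes the L_AT x N_mt / L_AT x L_ntx stratified histograms.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, pipeline_config  # noqa: E402

from pombeori.pipeline import run_stage  # noqa: E402


def main() -> None:
    cfg = pipeline_config()
    run_stage("features", cfg, RESULTS / "features")
    cfg.paths["features"] = str(RESULTS / "features" / "features.tsv")
    run_stage("train-eval", cfg, RESULTS / "cv")

    summary = json.loads((RESULTS / "cv" / "summary.json").read_text())
    print("repeated stratified CV (mean AUC [95% CI of round means]):")
    for name, entry in summary["feature_sets"].items():
        print(f"  {name:10s} ROC {entry['roc_auc_mean']:.3f} "
              f"[{entry['roc_auc_ci'][0]:.3f}, {entry['roc_auc_ci'][1]:.3f}]  "
              f"PR {entry['pr_auc_mean']:.3f} "
              f"[{entry['pr_auc_ci'][0]:.3f}, {entry['pr_auc_ci'][1]:.3f}]")
    fscores = pd.Series(summary["fscores"]).sort_values(ascending=False)
    print("feature F-scores (positive vs negative IGR discrimination):")
    print(fscores.to_string(float_format="%.3f"))
    trio = summary["feature_sets"]["trio"]
    print(f"median trio probability: OM IGRs {trio['median_prob_positive']:.3f}, "
          f"background {trio['median_prob_negative']:.4f}, held-out O "
          f"{trio.get('median_prob_heldout_O', float('nan')):.3f}")

    strata = pd.read_csv(RESULTS / "report" / "strata.tsv", sep="\t")
    nmt = strata[strata["second_feature"] == "N_mt"]
    pivot = nmt.pivot_table(index=["L_AT_stratum", "second_stratum"],
                            columns="class", values="count", aggfunc="sum")
    print("IGR counts per (L_AT stratum x N_mt stratum):")
    print(pivot.to_string())


if __name__ == "__main__":
    main()
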