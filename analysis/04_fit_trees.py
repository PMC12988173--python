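"""Fit one C&RT cut-off tree per pairwise comparison (each patient group
vs HC, plus FEP/CS, SA/CS, BD/SA) on the surviving features, and evaluate
each tree's training ROC-AUC.

Writes tree JSONs, ROC curve points and an AUC summary under results/trees/.
"""

from pathlib import Path

import pandas as pd

from skinrems.io import read_feature_csv, read_metadata_csv, write_tree_json
from skinrems.tree import TreeParams, build_tree, predict_table, roc_auc
from skinrems.workflow import DEFAULT_COMPARISONS

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main():
    features = read_feature_csv(SCRATCH / "features.csv")
    metadata = read_metadata_csv(RESULTS / "metadata.csv").loc[features.index]
    survivors = pd.read_csv(RESULTS / "survivors.csv")["feature"].tolist()
    out = RESULTS / "trees"
    out.mkdir(exist_ok=True)

    rows = []
    for comparison, le_group, gt_group in DEFAULT_COMPARISONS:
        idx = metadata.index[metadata["group"].isin({le_group, gt_group})]
        X = features.loc[idx, survivors]
        y = metadata.loc[idx, "group"]
        tree = build_tree(X, y, TreeParams(min_leaf=5, max_depth=3), pos_label=le_group)
        preds = predict_table(tree, X)
        roc = roc_auc(preds["score"].to_numpy(), y.to_numpy(), pos_label=le_group)
        write_tree_json(tree, out / f"tree_{comparison}.json")
        roc.curve_frame().to_csv(out / f"roc_{comparison}.csv", index=False)
        rows.append(
            {
                "comparison": comparison,
                "n_subjects": len(idx),
                "n_splits": len(tree.splits()),
                "root_feature": tree.splits()[0][0] if tree.splits() else None,
                "root_threshold": tree.splits()[0][1] if tree.splits() else None,
                "training_auc": round(roc.auc, 3),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "auc_summary.csv", index=False)
    print("fitted trees (training ROC-AUC on the synthetic cohort):")
    print(summary.to_string(index=False))
    print(f"\ntrees + ROC curves -> {out}")


if __name__ == "__main__":
    main()
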