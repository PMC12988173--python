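"""Feature selection in three steps: (1) screen for patient-vs-HC group
differences (Shapiro-Wilk gate choosing t vs Mann-Whitney, p < 0.05);
(2) exclude features associated with sociodemographic/lifestyle/health
factors in either group; (3) exclude features associated with
disease-related factors (illness duration, hospitalizations, olanzapine
equivalents, PANSS) among patients.

Writes the survivor list, the per-stage screening table and the exclusion
ledger under results/.
"""

from pathlib import Path

import pandas as pd

from skinrems.io import read_feature_csv, read_metadata_csv
from skinrems.selection import select_features

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main():
    features = read_feature_csv(SCRATCH / "features.csv")
    metadata = read_metadata_csv(RESULTS / "metadata.csv").loc[features.index]

    summary = select_features(features, metadata, alpha=0.05)

    pd.DataFrame({"feature": summary.survivors}).to_csv(RESULTS / "survivors.csv", index=False)
    summary.screening.table.to_csv(SCRATCH / "screening_full.csv", index=False)
    stage_counts = pd.DataFrame(
        {
            "stage": ["input", "screening", "confounder_exclusion", "disease_exclusion"],
            "n_features": [
                summary.n_input,
                summary.n_after_screening,
                summary.n_after_confound,
                summary.n_after_disease,
            ],
        }
    )
    stage_counts.to_csv(RESULTS / "stage_counts.csv", index=False)
    ledger = pd.concat(
        [
            summary.confound_ledger.records.assign(stage="confounder"),
            summary.disease_ledger.records.assign(stage="disease"),
        ],
        ignore_index=True,
    )
    ledger.to_csv(RESULTS / "exclusion_ledger.csv", index=False)

    n_nonnormal = (
        summary.screening.table[["normal_HC", "normal_PAT"]].eq(False).any(axis=1).sum()
    )
    print(
        f"variable accounting: {summary.n_input} -> {summary.n_after_screening} "
        f"(screening) -> {summary.n_after_confound} (confounder exclusion) -> "
        f"{summary.n_after_disease} (disease exclusion)"
    )
    print(f"features with a non-normal distribution in at least one group: {n_nonnormal}")
    if len(ledger):
        print("\nexclusions by factor:")
        print(ledger.groupby(["stage", "factor"])["feature"].nunique().to_string())
    print(f"\nsurvivors -> {RESULTS / 'survivors.csv'}")


if __name__ == "__main__":
    main()
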