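"""End-to-end orchestration: simulate -> extract -> select -> fit -> report.

``run_full`` executes the whole pipeline into a run directory and writes a
manifest (seed, config hash, library versions) so a run is reconstructible
from its manifest alone. Per-stage logs record counts in/out at every
filter, mirroring the step-wise variable accounting of the screening
procedure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as skio
from .config import PATIENT_GROUPS, CohortConfig, small_demo_config
from .errors import ConfigurationError, InputError
from .pipeline import build_feature_table, segment_rois
from .report import integrate_trees, render_report, summary_table
from .rules import tree_to_ruleset
from .selection import SelectionSummary, select_features
from .synthetic import generate_cohort, metadata_frame
from .tree import TreeParams, build_tree, predict_table, roc_auc

logger = logging.getLogger(__name__)

#: The pairwise comparisons fitted by default, as (comparison name,
#: blunted-side group, stronger-flush group).
DEFAULT_COMPARISONS: Tuple[Tuple[str, str, str], ...] = (
    ("FEP_vs_HC", "FEP", "HC"),
    ("CS_vs_HC", "CS", "HC"),
    ("SA_vs_HC", "SA", "HC"),
    ("BD_vs_HC", "BD", "HC"),
    ("FEP_vs_CS", "CS", "FEP"),
    ("SA_vs_CS", "CS", "SA"),
    ("BD_vs_SA", "SA", "BD"),
)


@dataclass
class RunConfig:
    out_dir: Path
    cohort: CohortConfig = field(default_factory=lambda: small_demo_config())
    alpha: float = 0.05
    tree_params: TreeParams = field(default_factory=TreeParams)
    comparisons: Sequence[Tuple[str, str, str]] = DEFAULT_COMPARISONS
    use_ground_truth_rois: bool = False
    write_frames: bool = False
    seed: Optional[int] = None  # overrides cohort.seed when set

    def effective_seed(self) -> int:
        return self.cohort.seed if self.seed is None else int(self.seed)


@dataclass
class RunResult:
    out_dir: Path
    features: pd.DataFrame
    metadata: pd.DataFrame
    selection: SelectionSummary
    trees: Dict[str, object]
    rocs: Dict[str, object]
    report_path: Path
    manifest: dict


def _config_hash(config: CohortConfig) -> str:
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_full(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write every artifact under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.effective_seed())

    # --- simulate ---------------------------------------------------------
    metadata_list, sequences, truths = generate_cohort(cohort_cfg)
    meta_df = metadata_frame(metadata_list)
    skio.write_metadata_csv(meta_df, out / "metadata.csv")
    logger.info("simulate: %d subjects, %d sequences", len(metadata_list), len(sequences))
    if config.write_frames:
        by_sid = {}
        for seq in sequences:
            by_sid.setdefault(seq.subject_id, seq)  # frames shared across concentrations
        for sid, seq in by_sid.items():
            skio.write_frames(seq, out / "frames" / sid)

    # --- extract ----------------------------------------------------------
    truth_by_sid = {t.subject_id: t for t in truths}
    rois = {}
    peak_idx = int(np.argmin(np.abs(cohort_cfg.frame_times - cohort_cfg.kernel.peak_time)))
    for sid, truth in truth_by_sid.items():
        if config.use_ground_truth_rois:
            rois[sid] = truth.roi_set()
        else:
            seq = next(s for s in sequences if s.subject_id == sid)
            rois[sid] = segment_rois(seq.frames[peak_idx], cohort_cfg.layout)
    features, exclusions = build_feature_table(
        sequences, rois, concentrations=cohort_cfg.concentrations
    )
    skio.write_feature_csv(features, out / "features.csv")
    logger.info(
        "extract: %d subjects x %d features (%d excluded)",
        *features.shape,
        len(exclusions),
    )

    # --- select -----------------------------------------------------------
    meta_aligned = meta_df.loc[features.index]
    selection = select_features(features, meta_aligned, alpha=config.alpha)
    pd.DataFrame({"feature": selection.survivors}).to_csv(out / "survivors.csv", index=False)
    selection.screening.table.to_csv(out / "screening.csv", index=False)
    ledger = pd.concat(
        [
            selection.confound_ledger.records.assign(stage="confounder"),
            selection.disease_ledger.records.assign(stage="disease"),
        ],
        ignore_index=True,
    )
    ledger.to_csv(out / "exclusion_ledger.csv", index=False)

    # --- fit + ROC per comparison ----------------------------------------
    trees, rocs, rulesets = {}, {}, []
    survivors = selection.survivors
    for comparison, le_group, gt_group in config.comparisons:
        pair = {le_group, gt_group}
        idx = meta_aligned.index[meta_aligned["group"].isin(pair)]
        if len(idx) == 0 or meta_aligned.loc[idx, "group"].nunique() < 2:
            logger.info("fit %s: skipped (groups absent)", comparison)
            continue
        X = features.loc[idx, survivors]
        y = meta_aligned.loc[idx, "group"]
        tree = build_tree(X, y, params=config.tree_params, pos_label=le_group)
        preds = predict_table(tree, X)
        roc = roc_auc(preds["score"].to_numpy(), y.to_numpy(), pos_label=le_group)
        trees[comparison] = tree
        rocs[comparison] = roc
        rulesets.append(tree_to_ruleset(tree, comparison, le_group, gt_group, auc=roc.auc))
        skio.write_tree_json(tree, out / f"tree_{comparison}.json", seed=cohort_cfg.seed)
        roc.curve_frame().to_csv(out / f"roc_{comparison}.csv", index=False)
        logger.info("fit %s: %d splits, training AUC %.3f", comparison, len(tree.splits()), roc.auc)

    # --- integrate + report ----------------------------------------------
    report_path = out / "report.md"
    if rulesets:
        integration = integrate_trees(rulesets)
        integration.ledger_frame().to_csv(out / "integration_ledger.csv", index=False)
        table = summary_table(rulesets, rocs)
        table.to_csv(out / "summary_table.csv", index=False)
        report_path.write_text(render_report(table, integration, title="Fitted NSFT classification summary"))
    else:
        report_path.write_text("# Fitted NSFT classification summary\n\nNo comparisons could be fitted.\n")

    # --- manifest ---------------------------------------------------------
    import scipy
    import skimage

    manifest = {
        "seed": cohort_cfg.seed,
        "config_hash": _config_hash(cohort_cfg),
        "cohort_config": cohort_cfg.to_dict(),
        "alpha": config.alpha,
        "tree_params": dataclasses.asdict(config.tree_params),
        "comparisons": [list(c) for c in config.comparisons],
        "n_subjects": int(len(meta_df)),
        "n_features": int(features.shape[1]),
        "n_survivors": len(survivors),
        "excluded_subjects": [list(e) for e in exclusions],
        "stage_counts": {
            "input": selection.n_input,
            "after_screening": selection.n_after_screening,
            "after_confounder_exclusion": selection.n_after_confound,
            "after_disease_exclusion": selection.n_after_disease,
        },
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(
        out_dir=out,
        features=features,
        metadata=meta_df,
        selection=selection,
        trees=trees,
        rocs=rocs,
        report_path=report_path,
        manifest=manifest,
    )
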