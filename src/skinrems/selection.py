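"""Multi-step feature screening with confounder and disease-factor exclusion.

Three stages, applied in a fixed order, each consuming the survivors of the
previous one:

1. ``screen_group_differences`` — keep features that differ between
   patients and healthy controls (Shapiro-Wilk normality gate choosing
   Student's t vs Mann-Whitney U; raw p < alpha, no multiplicity
   correction by default).
2. ``exclude_confounded`` — drop any feature associated with a
   sociodemographic/lifestyle/health factor in EITHER the patient or the
   control group, regardless of effect size.
3. ``exclude_disease_related`` — drop any surviving feature associated
   with illness duration, hospitalizations, antipsychotic dose
   (olanzapine equivalents) or symptom severity (PANSS), assessed in the
   patient group only.

Association tests: continuous factor -> Pearson correlation when both the
feature and the factor pass Shapiro-Wilk in that group, else Spearman;
binary factor -> Mann-Whitney U on the feature across factor levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .synthetic import BINARY_FACTORS, DISEASE_FACTORS, SOCIODEMOGRAPHIC_FACTORS

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk gate; constant samples count as non-normal."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue >= alpha


@dataclass
class ScreeningResult:
    """Per-feature screening outcome (stage 1)."""

    table: pd.DataFrame  # feature, normal_hc, normal_pat, test, p, selected
    alpha: float

    @property
    def selected(self) -> List[str]:
        return list(self.table.loc[self.table["selected"], "feature"])


def screen_group_differences(
    features: pd.DataFrame,
    labels: pd.Series,
    alpha: float = DEFAULT_ALPHA,
) -> ScreeningResult:
    """Stage 1: keep features that differ between the two label classes.

    Both classes must have n >= 3. A feature constant in both classes is
    flagged 'degenerate' and never selected.
    """
    labels = labels.reindex(features.index)
    classes = sorted(labels.dropna().unique())
    if len(classes) != 2:
        raise InputError(f"need exactly two label classes, got {classes}")
    g0 = features.loc[labels == classes[0]]
    g1 = features.loc[labels == classes[1]]
    if len(g0) < 3 or len(g1) < 3:
        raise InputError("each class needs at least 3 subjects")

    rows = []
    for col in features.columns:
        x0 = g0[col].to_numpy(dtype=float)
        x1 = g1[col].to_numpy(dtype=float)
        if np.ptp(x0) == 0 and np.ptp(x1) == 0:
            rows.append((col, False, False, "degenerate", np.nan, False))
            continue
        n0 = _is_normal(x0, alpha)
        n1 = _is_normal(x1, alpha)
        if n0 and n1:
            p = float(stats.ttest_ind(x0, x1).pvalue)
            test = "t"
        else:
            p = float(stats.mannwhitneyu(x0, x1, alternative="two-sided").pvalue)
            test = "mannwhitney"
        rows.append((col, n0, n1, test, p, bool(p < alpha)))
    table = pd.DataFrame(
        rows, columns=["feature", f"normal_{classes[0]}", f"normal_{classes[1]}", "test", "p", "selected"]
    )
    return ScreeningResult(table=table, alpha=alpha)


@dataclass
class ExclusionLedger:
    """Stage 2/3 outcome: removed features with their triggering associations."""

    records: pd.DataFrame  # feature, factor, group, test, p (one row per trigger)
    survivors: List[str]
    removed: List[str] = field(default_factory=list)
    skipped: List[Tuple[str, str, str]] = field(default_factory=list)  # factor, group, reason

    def triggers(self, feature: str) -> pd.DataFrame:
        return self.records.loc[self.records["feature"] == feature]


def _associate(
    feature_values: np.ndarray,
    factor_values: np.ndarray,
    factor: str,
    alpha: float,
) -> Optional[Tuple[str, float]]:
    """(test name, p-value) for one feature-factor association, or None if
    the test is not applicable (constant factor / level too small)."""
    x = np.asarray(feature_values, dtype=float)
    f = np.asarray(factor_values, dtype=float)
    keep = ~np.isnan(f) & ~np.isnan(x)
    x, f = x[keep], f[keep]
    if x.size < 3 or np.ptp(f) == 0:
        return None
    if factor in BINARY_FACTORS:
        levels = np.unique(f)
        if len(levels) != 2:
            return None
        a = x[f == levels[0]]
        b = x[f == levels[1]]
        if len(a) < 2 or len(b) < 2:
            return None
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        return ("mannwhitney", p)
    if np.ptp(x) == 0:
        return None
    if _is_normal(x, alpha) and _is_normal(f, alpha):
        r = stats.pearsonr(x, f)
        return ("pearson", float(r.pvalue))
    r = stats.spearmanr(x, f)
    return ("spearman", float(r.pvalue))


def _exclusion_pass(
    features: pd.DataFrame,
    groups: Dict[str, pd.Index],
    metadata: pd.DataFrame,
    factors: Sequence[str],
    alpha: float,
) -> ExclusionLedger:
    records = []
    skipped = []
    for group_name, idx in groups.items():
        sub_meta = metadata.loc[idx]
        sub_feat = features.loc[idx]
        for factor in factors:
            if factor not in metadata.columns:
                raise InputError(f"factor {factor!r} absent from metadata")
            fvals = pd.to_numeric(sub_meta[factor], errors="coerce").to_numpy()
            if np.all(np.isnan(fvals)) or np.ptp(fvals[~np.isnan(fvals)]) == 0:
                skipped.append((factor, group_name, "constant or missing within group"))
                logger.info("skipping factor %s in group %s: constant/missing", factor, group_name)
                continue
            for col in features.columns:
                res = _associate(sub_feat[col].to_numpy(dtype=float), fvals, factor, alpha)
                if res is None:
                    continue
                test, p = res
                if p < alpha:
                    records.append((col, factor, group_name, test, p))
    rec_df = pd.DataFrame(records, columns=["feature", "factor", "group", "test", "p"])
    removed = sorted(rec_df["feature"].unique()) if len(rec_df) else []
    survivors = [c for c in features.columns if c not in set(removed)]
    return ExclusionLedger(records=rec_df, survivors=survivors, removed=removed, skipped=skipped)


def exclude_confounded(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    factors: Sequence[str] = SOCIODEMOGRAPHIC_FACTORS,
    alpha: float = DEFAULT_ALPHA,
    group_col: str = "group",
) -> ExclusionLedger:
    """Stage 2: drop features tied to sociodemographic/lifestyle factors.

    Associations are assessed separately in the pooled patient group and in
    healthy controls; a single significant association in either group
    removes the feature, independently of its strength.
    """
    metadata = metadata.loc[features.index]
    is_hc = metadata[group_col] == "HC"
    groups = {"patients": features.index[~is_hc], "HC": features.index[is_hc]}
    groups = {k: v for k, v in groups.items() if len(v) > 0}
    return _exclusion_pass(features, groups, metadata, factors, alpha)


def exclude_disease_related(
    features: pd.DataFrame,
    patient_metadata: pd.DataFrame,
    factors: Sequence[str] = DISEASE_FACTORS,
    alpha: float = DEFAULT_ALPHA,
    group_col: str = "group",
) -> ExclusionLedger:
    """Stage 3: drop features tied to disease-related factors (patients only)."""
    if len(patient_metadata) == 0:
        raise InputError("no patient rows supplied")
    if (patient_metadata[group_col] == "HC").any():
        raise InputError("disease-related exclusion must be run on patients only")
    patient_metadata = patient_metadata.loc[features.index]
    groups = {"patients": features.index}
    return _exclusion_pass(features, groups, patient_metadata, factors, alpha)


@dataclass
class SelectionSummary:
    """Counts in/out at every stage of the selection pipeline."""

    n_input: int
    n_after_screening: int
    n_after_confound: int
    n_after_disease: int
    screening: ScreeningResult = None
    confound_ledger: ExclusionLedger = None
    disease_ledger: ExclusionLedger = None

    @property
    def survivors(self) -> List[str]:
        return self.disease_ledger.survivors


def select_features(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    group_col: str = "group",
) -> SelectionSummary:
    """Run the full screening -> confounder -> disease pipeline."""
    metadata = metadata.loc[features.index]
    labels = (metadata[group_col] == "HC").map({True: "HC", False: "PAT"})
    screening = screen_group_differences(features, labels, alpha)
    stage1 = features[screening.selected]
    logger.info("screening: %d -> %d features", features.shape[1], stage1.shape[1])

    confound = exclude_confounded(stage1, metadata, alpha=alpha, group_col=group_col)
    stage2 = stage1[confound.survivors]
    logger.info("confounder exclusion: %d -> %d features", stage1.shape[1], stage2.shape[1])

    patients = metadata.index[metadata[group_col] != "HC"]
    if len(patients) and stage2.shape[1]:
        disease = exclude_disease_related(
            stage2.loc[patients], metadata.loc[patients], alpha=alpha, group_col=group_col
        )
    else:
        disease = ExclusionLedger(
            records=pd.DataFrame(columns=["feature", "factor", "group", "test", "p"]),
            survivors=list(stage2.columns),
        )
    logger.info("disease exclusion: %d -> %d features", stage2.shape[1], len(disease.survivors))
    return SelectionSummary(
        n_input=features.shape[1],
        n_after_screening=stage1.shape[1],
        n_after_confound=stage2.shape[1],
        n_after_disease=len(disease.survivors),
        screening=screening,
        confound_ledger=confound,
        disease_ledger=disease,
    )
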