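"""Machine-readable encoding of the published NSFT decision rules.

Seven pairwise comparisons, each a short cascade of "<= cut-off" splits on
differential colour features at 0.1 M. Feature coordinates follow the
``<channel><statistic>_<index>_<code>`` convention (index n <-> n - 0.5
minutes; A = 0.1 M). Where the published summary table and the narrative
text disagree on a time point or statistic, the table's coordinates are
kept and the discrepancy is recorded in the rule's ``note``.

Leaf semantics: every rule's "<=" side is the blunted-response branch; a
record exits to the stronger-flush group at the first "> cut-off" and is
assigned the blunted-side group only if it falls at or below every
cut-off. For patient-vs-patient comparisons the blunted side is the more
chronic group (CS against FEP/SA; SA against BD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Tuple

import pandas as pd

from .errors import InputError
from .pipeline import feature_key

CODE_TO_MOLARITY = {"A": 0.1, "B": 0.01, "C": 0.001}
CHANNEL_NAMES = {"R": "Red", "G": "Green", "B": "Blue"}


@dataclass(frozen=True)
class Rule:
    """One binary split: feature coordinates, cut-off, '<=' direction."""

    channel: str
    statistic: str
    time_index: int
    concentration_code: str
    threshold: float
    note: str = ""

    @property
    def time_minutes(self) -> float:
        return self.time_index - 0.5

    @property
    def concentration_molar(self) -> float:
        return CODE_TO_MOLARITY[self.concentration_code]

    @property
    def feature_key(self) -> str:
        return feature_key(self.channel, self.statistic, self.time_index, self.concentration_code)


@dataclass
class RuleSet:
    """An ordered cut-off cascade for one pairwise comparison."""

    comparison: str
    le_label: str  # class assigned when every '<=' holds (blunted side)
    gt_label: str  # class assigned at the first '>'
    rules: List[Rule]
    auc: Optional[float] = None
    source: str = "fitted"
    notes: List[str] = field(default_factory=list)

    def feature_keys(self) -> List[str]:
        return [r.feature_key for r in self.rules]


def apply_rules(ruleset: RuleSet, record: Mapping[str, float]):
    """Sequential <=-threshold routing; returns the assigned group label."""
    for rule in ruleset.rules:
        key = rule.feature_key
        if key not in record:
            raise InputError(f"record missing feature {key!r}")
        if record[key] > rule.threshold:
            return ruleset.gt_label
    return ruleset.le_label


def published_rules() -> List[RuleSet]:
    """The published cut-off rules of the seven pairwise comparisons.

    All splits use the 0.1 M concentration. Statistics come from the
    narrative results (mean vs median vs max); coordinates with a
    table-vs-text discrepancy carry an explanatory note.
    """
    return [
        RuleSet(
            comparison="FEP_vs_HC",
            le_label="FEP",
            gt_label="HC",
            auc=0.80,
            source="published",
            rules=[
                Rule("G", "mean", 3, "A", 12.53),
                Rule("B", "mean", 6, "A", 23.24),
            ],
        ),
        RuleSet(
            comparison="CS_vs_HC",
            le_label="CS",
            gt_label="HC",
            auc=0.90,
            source="published",
            rules=[
                Rule("B", "median", 3, "A", 25.50),
                Rule("R", "median", 3, "A", 20.50),
                Rule("B", "mean", 6, "A", 4.19),
            ],
        ),
        RuleSet(
            comparison="SA_vs_HC",
            le_label="SA",
            gt_label="HC",
            auc=0.79,
            source="published",
            rules=[
                Rule("G", "mean", 4, "A", 3.20),
                Rule("B", "median", 4, "A", 13.5),
            ],
        ),
        RuleSet(
            comparison="BD_vs_HC",
            le_label="BD",
            gt_label="HC",
            auc=0.64,
            source="published",
            rules=[Rule("G", "mean", 4, "A", 6.02)],
        ),
        RuleSet(
            comparison="FEP_vs_CS",
            le_label="CS",
            gt_label="FEP",
            auc=0.86,
            source="published",
            rules=[
                Rule("G", "mean", 3, "A", 26.65),
                Rule(
                    "B",
                    "mean",
                    6,
                    "A",
                    3.34,
                    note="statistic not named in the narrative; mean assumed",
                ),
            ],
        ),
        RuleSet(
            comparison="SA_vs_CS",
            le_label="CS",
            gt_label="SA",
            auc=0.89,
            source="published",
            rules=[
                Rule("G", "mean", 3, "A", 36.77),
                Rule(
                    "G",
                    "mean",
                    5,
                    "A",
                    22.94,
                    note="summary table time 4.5 min kept; narrative says 5.5 min",
                ),
                Rule("B", "mean", 6, "A", 16.80),
            ],
            notes=["table coordinates kept over narrative for the 22.94 cut-off"],
        ),
        RuleSet(
            comparison="BD_vs_SA",
            le_label="SA",
            gt_label="BD",
            auc=0.80,
            source="published",
            rules=[
                Rule("G", "max", 3, "A", 21.50),
                Rule(
                    "G",
                    "mean",
                    4,
                    "A",
                    2.82,
                    note="narrative names mean/median at 3.5 and 5.5 min; table times kept",
                ),
                Rule(
                    "G",
                    "median",
                    5,
                    "A",
                    15.50,
                    note="narrative names mean/median at 3.5 and 5.5 min; table times kept",
                ),
            ],
            notes=["table coordinates kept over narrative for the later cut-offs"],
        ),
    ]


def rules_to_frame(rulesets: List[RuleSet]) -> pd.DataFrame:
    """Summary-table layout: one row per (comparison, split)."""
    rows = []
    for rs in rulesets:
        for rule in rs.rules:
            rows.append(
                {
                    "comparison": rs.comparison.replace("_vs_", " vs. "),
                    "color_channel": CHANNEL_NAMES.get(rule.channel, rule.channel),
                    "statistic": rule.statistic,
                    "time_minutes": rule.time_minutes,
                    "concentration": f"{rule.concentration_molar:g} M",
                    "cutoff": rule.threshold,
                    "roc_auc": rs.auc,
                    "le_branch_label": rs.le_label,
                    "gt_branch_label": rs.gt_label,
                    "source": rs.source,
                    "note": rule.note,
                }
            )
    return pd.DataFrame(rows)


def tree_to_ruleset(tree, comparison: str, le_label, gt_label, auc=None) -> RuleSet:
    """Flatten a fitted DecisionTree's splits (pre-order) into a RuleSet.

    Used for cross-tree integration and reporting; the cascade preserves
    the (feature, threshold) pairs but not the full branch topology, so it
    is a summary of the tree's cut-offs, not a prediction-equivalent form.
    """
    from .pipeline import parse_feature_key

    rules = []
    for feature, threshold in tree.splits():
        channel, stat, idx, code = parse_feature_key(feature)
        rules.append(Rule(channel, stat, idx, code, float(threshold)))
    return RuleSet(
        comparison=comparison,
        le_label=le_label,
        gt_label=gt_label,
        rules=rules,
        auc=auc,
        source="fitted",
    )
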