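"""Cross-tree integration and the summary report.

After fitting one tree per pairwise comparison, variables that recur in
two or more comparisons' rule sets are dropped; the remainder are the
variables characteristic of each comparison. "Repeated within two groups"
is read as "appears in >= 2 pairwise comparisons' rule sets" — the single
interpretation this package implements (flagged in the report output).
Integration runs after ROC evaluation, so reported AUCs reflect the full
trees; it changes variable membership lists only, never thresholds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import pandas as pd

from .errors import InputError
from .rules import RuleSet, rules_to_frame

INTERPRETATION_NOTE = (
    "shared variables = variables appearing in the rule sets of >= 2 pairwise comparisons"
)


@dataclass
class IntegrationResult:
    """Shared (removed) vs comparison-characteristic variables."""

    removed: List[str]
    characteristic: Dict[str, List[str]]  # comparison -> retained variables
    occurrences: Dict[str, List[str]]  # variable -> comparisons containing it

    def ledger_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": var,
                "comparisons": ";".join(comps),
                "n_comparisons": len(comps),
                "removed": var in set(self.removed),
            }
            for var, comps in sorted(self.occurrences.items())
        ]
        return pd.DataFrame(rows)


def integrate_trees(rulesets: List[RuleSet]) -> IntegrationResult:
    """Drop variables shared between comparisons; keep the characteristic ones."""
    if not rulesets:
        raise InputError("need at least one ruleset to integrate")
    occurrences: Dict[str, List[str]] = {}
    for rs in rulesets:
        for key in sorted(set(rs.feature_keys())):
            occurrences.setdefault(key, []).append(rs.comparison)
    removed = sorted(v for v, comps in occurrences.items() if len(comps) >= 2)
    removed_set = set(removed)
    characteristic = {
        rs.comparison: sorted(set(rs.feature_keys()) - removed_set) for rs in rulesets
    }
    return IntegrationResult(removed=removed, characteristic=characteristic, occurrences=occurrences)


def summary_table(
    rulesets: List[RuleSet],
    roc_results: Optional[Mapping[str, object]] = None,
) -> pd.DataFrame:
    """One row per (comparison, split), mirroring the published summary layout.

    In fitted mode pass ``roc_results`` (comparison -> RocResult) and the
    AUC column is recomputed from predictions; in published mode the
    encoded AUCs are used.
    """
    if roc_results is not None:
        missing = {rs.comparison for rs in rulesets} ^ set(roc_results)
        if missing:
            raise InputError(f"comparisons mismatch between rulesets and ROC results: {sorted(missing)}")
        rulesets = [
            RuleSet(
                comparison=rs.comparison,
                le_label=rs.le_label,
                gt_label=rs.gt_label,
                rules=rs.rules,
                auc=float(roc_results[rs.comparison].auc),
                source=rs.source,
                notes=rs.notes,
            )
            for rs in rulesets
        ]
    return rules_to_frame(rulesets)


def _markdown_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = ["" if pd.isna(v) else (f"{v:g}" if isinstance(v, float) else str(v)) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def render_report(
    table: pd.DataFrame,
    integration: Optional[IntegrationResult] = None,
    title: str = "NSFT classification summary",
) -> str:
    """Markdown report: summary table plus the integration ledger."""
    parts = [f"# {title}", "", _markdown_table(table), ""]
    if integration is not None:
        parts += [
            "## Cross-tree integration",
            "",
            f"Interpretation: {INTERPRETATION_NOTE}.",
            "",
            f"Shared variables removed: {', '.join(integration.removed) or 'none'}",
            "",
        ]
        for comp, kept in sorted(integration.characteristic.items()):
            parts.append(f"- characteristic of {comp}: {', '.join(kept) or 'none'}")
        parts.append("")
    return "\n".join(parts)
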