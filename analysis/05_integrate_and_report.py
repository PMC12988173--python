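"""Integrate the fitted trees (drop variables shared by >= 2 comparisons,
keep the comparison-characteristic ones) and render the summary report,
alongside the packaged published rule set for side-by-side comparison.

Writes results/report.md, the summary tables and the integration ledger.
"""

from pathlib import Path

import pandas as pd

from skinrems.io import read_tree_json
from skinrems.report import integrate_trees, render_report, summary_table
from skinrems.rules import published_rules, rules_to_frame, tree_to_ruleset
from skinrems.tree import roc_auc  # noqa: F401  (re-exported context for readers)
from skinrems.workflow import DEFAULT_COMPARISONS

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    aucs = pd.read_csv(RESULTS / "trees" / "auc_summary.csv").set_index("comparison")
    rulesets = []
    for comparison, le_group, gt_group in DEFAULT_COMPARISONS:
        tree = read_tree_json(RESULTS / "trees" / f"tree_{comparison}.json")
        rulesets.append(
            tree_to_ruleset(
                tree, comparison, le_group, gt_group, auc=float(aucs.loc[comparison, "training_auc"])
            )
        )

    integration = integrate_trees(rulesets)
    fitted_table = rules_to_frame(rulesets)
    fitted_table.to_csv(RESULTS / "fitted_summary_table.csv", index=False)
    integration.ledger_frame().to_csv(RESULTS / "integration_ledger.csv", index=False)

    pub = published_rules()
    pub_table = rules_to_frame(pub)
    pub_table.to_csv(RESULTS / "published_rules.csv", index=False)

    report = render_report(fitted_table, integration, title="Fitted NSFT classification summary (synthetic cohort)")
    report += "\n\n## Published rule set (encoded)\n\n"
    report += render_report(pub_table, integrate_trees(pub), title="Published NSFT classification rules")
    (RESULTS / "report.md").write_text(report)

    print(f"fitted splits: {len(fitted_table)} across {len(rulesets)} comparisons")
    print(f"variables shared between >= 2 comparisons (removed): {len(integration.removed)}")
    for comp, kept in sorted(integration.characteristic.items()):
        print(f"  characteristic of {comp}: {', '.join(kept) or '(none)'}")
    print(f"\nreport -> {RESULTS / 'report.md'}")


if __name__ == "__main__":
    main()
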