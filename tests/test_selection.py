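"""Screening and exclusion stages: planted effects, calibration, invariances."""

import numpy as np
import pandas as pd
import pytest

from skinrems.errors import InputError
from skinrems.selection import (
    exclude_confounded,
    exclude_disease_related,
    screen_group_differences,
    select_features,
)
from skinrems.synthetic import (
    metadata_frame,
    simulate_confounded_matrix,
    simulate_screening_matrix,
)
from skinrems.config import CohortConfig


def cohort_metadata(seed=5, sizes=None):
    from skinrems.synthetic import _sample_metadata

    rng = np.random.default_rng(seed)
    sizes = sizes or {"FEP": 40, "HC": 40}
    metas = []
    i = 0
    for group, n in sizes.items():
        for _ in range(n):
            metas.append(_sample_metadata(f"S{i:03d}", group, rng))
            i += 1
    return metadata_frame(metas)


class TestScreening:
    def test_constant_feature_flagged_degenerate(self):
        X = pd.DataFrame({"flat": np.ones(20), "vary": np.r_[np.zeros(10), np.ones(10)]})
        labels = pd.Series(["HC"] * 10 + ["PAT"] * 10, index=X.index)
        res = screen_group_differences(X, labels)
        row = res.table.set_index("feature").loc["flat"]
        assert row["test"] == "degenerate"
        assert not row["selected"]

    def test_planted_large_effect_selected(self):
        X, labels = simulate_screening_matrix(n_null=5, n_signal=5, effect=3.0, seed=1)
        res = screen_group_differences(X, labels)
        sel = set(res.selected)
        assert {f"signal_{i}" for i in range(5)} <= sel

    def test_type_one_error_calibrated(self):
        """Null selection rate within binomial 99% bounds of alpha=0.05."""
        X, labels = simulate_screening_matrix(n_null=1000, n_signal=0, seed=2)
        res = screen_group_differences(X, labels)
        rate = len(res.selected) / 1000
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < half_width

    def test_normality_gate_routes_to_mannwhitney(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"skewed": np.exp(rng.normal(0, 1.5, 60)), "gauss": rng.normal(0, 1, 60)})
        labels = pd.Series(["HC"] * 30 + ["PAT"] * 30, index=X.index)
        res = screen_group_differences(X, labels).table.set_index("feature")
        assert res.loc["skewed", "test"] == "mannwhitney"
        assert res.loc["gauss", "test"] == "t"

    def test_row_and_column_order_invariance(self):
        X, labels = simulate_screening_matrix(n_null=30, n_signal=5, seed=4)
        res1 = screen_group_differences(X, labels)
        rng = np.random.default_rng(0)
        perm_rows = rng.permutation(X.index)
        perm_cols = rng.permutation(X.columns)
        res2 = screen_group_differences(X.loc[perm_rows, perm_cols], labels.loc[perm_rows])
        t1 = res1.table.set_index("feature").sort_index()
        t2 = res2.table.set_index("feature").sort_index()
        pd.testing.assert_frame_equal(t1, t2)

    def test_requires_two_classes_of_three(self):
        X = pd.DataFrame({"a": np.arange(6.0)})
        with pytest.raises(InputError):
            screen_group_differences(X, pd.Series(["HC"] * 6, index=X.index))
        with pytest.raises(InputError):
            screen_group_differences(X, pd.Series(["HC", "HC", "PAT", "PAT", "PAT", "PAT"], index=X.index).iloc[:4])


class TestConfounderExclusion:
    def test_planted_bmi_feature_removed_with_ledger_citation(self):
        meta = cohort_metadata(seed=6)
        rng = np.random.default_rng(7)
        X = pd.DataFrame(
            {
                "tracks_bmi": meta["bmi"].to_numpy() + rng.normal(0, 0.5, len(meta)),
                "independent": rng.normal(0, 1, len(meta)),
            },
            index=meta.index,
        )
        ledger = exclude_confounded(X, meta)
        assert "tracks_bmi" in ledger.removed
        assert "bmi" in set(ledger.triggers("tracks_bmi")["factor"])
        assert "independent" in ledger.survivors

    def test_sensitivity_and_specificity_on_planted_matrix(self):
        meta = cohort_metadata(seed=8)
        X = simulate_confounded_matrix(meta, "bmi", n_confounded=60, n_clean=60, beta=1.0, seed=9)
        ledger = exclude_confounded(X, meta, factors=("bmi",))
        removed = set(ledger.removed)
        sens = sum(f"conf_{i}" in removed for i in range(60)) / 60
        spec = sum(f"clean_{i}" not in removed for i in range(60)) / 60
        assert sens >= 0.95
        assert spec >= 0.80  # two groups x alpha=0.05 -> ~10% false removal

    def test_empty_factor_list_retains_everything(self):
        meta = cohort_metadata(seed=10)
        X = simulate_confounded_matrix(meta, "bmi", n_confounded=3, n_clean=3, seed=11)
        ledger = exclude_confounded(X, meta, factors=())
        assert ledger.removed == []
        assert len(ledger.records) == 0
        assert ledger.survivors == list(X.columns)

    def test_constant_factor_skipped_not_fatal(self):
        meta = cohort_metadata(seed=12)
        meta["smoking"] = 0  # constant everywhere
        rng = np.random.default_rng(13)
        X = pd.DataFrame({"f": rng.normal(size=len(meta))}, index=meta.index)
        ledger = exclude_confounded(X, meta, factors=("smoking",))
        assert ledger.survivors == ["f"]
        assert len(ledger.skipped) == 2  # skipped in both groups


class TestDiseaseExclusion:
    def test_panss_tracking_feature_removed(self):
        meta = cohort_metadata(seed=14, sizes={"FEP": 60})
        rng = np.random.default_rng(15)
        X = pd.DataFrame(
            {
                "tracks_panss": meta["panss_total"].to_numpy() / 10 + rng.normal(0, 0.5, len(meta)),
                "independent": rng.normal(0, 1, len(meta)),
            },
            index=meta.index,
        )
        ledger = exclude_disease_related(X, meta)
        assert "tracks_panss" in ledger.removed
        assert "panss_total" in set(ledger.triggers("tracks_panss")["factor"])
        assert "independent" in ledger.survivors

    def test_hc_rows_rejected(self):
        meta = cohort_metadata(seed=16, sizes={"FEP": 5, "HC": 5})
        X = pd.DataFrame({"f": np.arange(10.0)}, index=meta.index)
        with pytest.raises(InputError):
            exclude_disease_related(X, meta)

    def test_empty_patient_set_rejected(self):
        with pytest.raises(InputError):
            exclude_disease_related(pd.DataFrame({"f": []}), pd.DataFrame({"group": []}))


class TestPipelineOrder:
    def test_survivor_counts_monotone_and_nested(self):
        meta = cohort_metadata(seed=17)
        rng = np.random.default_rng(18)
        n = len(meta)
        X = pd.DataFrame(rng.normal(size=(n, 80)), index=meta.index, columns=[f"f{i}" for i in range(80)])
        # plant group signal in 20 features, BMI confounding in 10 of those
        pat = (meta["group"] != "HC").to_numpy()
        for i in range(20):
            X[f"f{i}"] += 2.0 * pat
        z = ((meta["bmi"] - meta["bmi"].mean()) / meta["bmi"].std()).to_numpy()
        for i in range(10):
            X[f"f{i}"] += 2.0 * z
        summary = select_features(X, meta)
        assert summary.n_input >= summary.n_after_screening >= summary.n_after_confound >= summary.n_after_disease
        assert set(summary.survivors) <= set(summary.confound_ledger.survivors)
        assert set(summary.confound_ledger.survivors) <= set(summary.screening.selected)
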