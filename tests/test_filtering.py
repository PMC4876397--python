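import numpy as np
import pandas as pd
import pytest

from gbiq.filtering import (
    FilterError,
    MedianIQRFilter,
    RecommendationError,
    median_iqr_filter,
    recommend_grid_size,
    scan_grid_sizes,
)
from gbiq.gridding import quantify
from gbiq.synthetic import generate_colony


def grid_matrix_from_features(med, iqr, channel="H33342"):
    n = len(med)
    return pd.DataFrame(
        {
            "image_id": "m",
            "grid_row": np.arange(1, n + 1),
            "grid_col": 1,
            "g": 20,
            f"{channel}_median": med,
            f"{channel}_iqr": iqr,
        }
    )


class TestMedianIQRFilter:
    def test_two_planted_classes_selects_bright_uniform(self, rng):
        # nucleus-like: high median, low IQR; boundary-like: low median, high IQR
        med = np.concatenate([rng.normal(180, 5, 60), rng.normal(40, 5, 60)])
        iqr = np.concatenate([rng.normal(8, 1, 60), rng.normal(90, 5, 60)])
        m = grid_matrix_from_features(med, iqr)
        res = median_iqr_filter(m, "H33342", k_range=(1, 4), seed=0)
        assert not res.fallback_used
        sel = res.selected
        assert len(sel) == 60
        assert (sel["H33342_median"] > 100).all()
        # both criteria hold post-hoc for the selection
        assert sel["H33342_median"].mean() > m["H33342_median"].mean()
        assert sel["H33342_iqr"].mean() < m["H33342_iqr"].mean()

    def test_fallback_when_no_class_meets_both(self, rng):
        # bright class is also the high-IQR class: criteria cannot both hold
        med = np.concatenate([rng.normal(180, 5, 50), rng.normal(40, 5, 50)])
        iqr = np.concatenate([rng.normal(90, 5, 50), rng.normal(8, 1, 50)])
        m = grid_matrix_from_features(med, iqr)
        res = median_iqr_filter(m, "H33342", k_range=(2, 3), seed=0)
        assert res.fallback_used
        assert len(res.selected_classes) == 1
        assert res.selected["H33342_median"].mean() > m["H33342_median"].mean()

    def test_no_nucleus_like_class_errors(self):
        # a single class: its mean equals the overall mean, strictly-greater fails
        m = grid_matrix_from_features(np.full(40, 100.0), np.full(40, 10.0))
        m["H33342_median"] += np.linspace(-1e-9, 1e-9, 40)
        m["H33342_iqr"] += np.linspace(-1e-9, 1e-9, 40)
        with pytest.raises((FilterError, Exception)):
            median_iqr_filter(m, "H33342", k_range=(1, 1), seed=0)

    def test_selected_is_subset_and_columns_appended(self, rng):
        scene = generate_colony(seed=0)
        m = quantify(scene.image, 20)
        res = median_iqr_filter(m, "H33342", seed=0)
        assert len(res.selected) < len(m)
        assert {"filter_class", "filter_selected"} <= set(res.matrix.columns)
        assert res.matrix["filter_selected"].sum() == len(res.selected)
        # re-filtering the selection never enlarges it
        res2 = median_iqr_filter(
            res.selected.drop(columns=["filter_class", "filter_selected"]),
            "H33342",
            seed=0,
        )
        assert len(res2.selected) <= len(res.selected)

    def test_criteria_hold_across_seeds_and_count_tracks_nuclei(self):
        # the selected-class size should be of the order of the nucleus
        # count: at a well-chosen g, below twice the 41 planted nuclei
        counts = []
        for seed in range(10):
            scene = generate_colony(seed=seed)
            m = quantify(scene.image, 20)
            res = median_iqr_filter(m, "H33342", seed=seed)
            sel = res.selected
            assert sel["H33342_median"].mean() > m["H33342_median"].mean()
            assert sel["H33342_iqr"].mean() < m["H33342_iqr"].mean()
            counts.append(len(sel))
        assert 41 <= np.mean(counts) < 2 * 41

    def test_missing_counterstain_columns(self, rng):
        m = grid_matrix_from_features(rng.uniform(0, 1, 10), rng.uniform(0, 1, 10))
        with pytest.raises(ValueError, match="DAPI"):
            MedianIQRFilter(counterstain="DAPI").fit(m)

    def test_transform_applies_fitted_selection(self, rng):
        med = np.concatenate([rng.normal(180, 5, 60), rng.normal(40, 5, 60)])
        iqr = np.concatenate([rng.normal(8, 1, 60), rng.normal(90, 5, 60)])
        m = grid_matrix_from_features(med, iqr)
        f = MedianIQRFilter("H33342", k_range=(2, 2), random_state=0).fit(m)
        fresh = grid_matrix_from_features(
            np.array([182.0, 41.0]), np.array([7.5, 88.0])
        )
        out = f.transform(fresh)
        assert list(out["H33342_median"]) == [182.0]


class TestGridSizeScan:
    def test_one_row_per_candidate(self):
        scene = generate_colony(seed=1)
        report = scan_grid_sizes(
            scene.image, "H33342", g_candidates=(16, 20, 30), seed=1,
            k_range=(1, 5),
        )
        assert list(report["g"]) == [16, 20, 30]
        assert list(report["n_grids"]) == [15 * 15, 12 * 12, 8 * 8]

    def test_degenerate_g_recorded_not_raised(self):
        scene = generate_colony(seed=1)
        report = scan_grid_sizes(
            scene.image, "H33342", g_candidates=(240,), seed=1
        )
        assert report.loc[0, "n_grids"] == 1
        assert report.loc[0, "error"] != ""


class TestRecommendation:
    def _paper_like_report(self):
        # the qualitative pattern of a grid-size scan on a 41-nucleus image:
        # small g oversamples nuclei, g=30 triggers the fallback, and of the
        # two survivors g=20 is brighter and more numerous than g=24
        return pd.DataFrame(
            [
                dict(g=8, n_grids=900, selected_classes="2", n_selected=260,
                     selected_mean_median=150.0, selected_mean_iqr=9.0,
                     fallback_used=False, error=""),
                dict(g=12, n_grids=400, selected_classes="1+3", n_selected=130,
                     selected_mean_median=155.0, selected_mean_iqr=10.0,
                     fallback_used=False, error=""),
                dict(g=20, n_grids=144, selected_classes="3", n_selected=67,
                     selected_mean_median=165.0, selected_mean_iqr=8.0,
                     fallback_used=False, error=""),
                dict(g=24, n_grids=100, selected_classes="2", n_selected=40,
                     selected_mean_median=160.0, selected_mean_iqr=9.0,
                     fallback_used=False, error=""),
                dict(g=30, n_grids=64, selected_classes="1", n_selected=20,
                     selected_mean_median=140.0, selected_mean_iqr=30.0,
                     fallback_used=True, error=""),
            ]
        )

    def test_paper_pattern_recommends_20(self):
        g, rationale = recommend_grid_size(self._paper_like_report(), nucleus_count=41)
        assert g == 20
        assert "g=8: excluded" in rationale
        assert "g=30: excluded" in rationale
        assert "g=20: recommended" in rationale

    def test_single_candidate_passes(self):
        rep = self._paper_like_report().iloc[[2]]
        g, _ = recommend_grid_size(rep, nucleus_count=41)
        assert g == 20

    def test_without_nucleus_count_oversampling_rule_skipped(self):
        g, rationale = recommend_grid_size(self._paper_like_report(), None)
        # ranking by brightness alone now keeps the small-g rows in play
        assert g == 20  # still brightest
        assert "multiple" not in rationale

    def test_all_excluded_raises_with_rationale(self):
        rep = self._paper_like_report().iloc[[0, 4]]
        with pytest.raises(RecommendationError, match="g=30"):
            recommend_grid_size(rep, nucleus_count=41)
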