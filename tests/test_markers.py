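"""Differential testing core: t-test, BH, discovery, ranking, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import hepamark as hm
from hepamark.markers import (
    bh_fdr,
    class_profile,
    discover_markers,
    flag_outliers,
    heatmap_matrix,
    rank_markers,
    ttest_equal_var,
)
from hepamark.preprocess import DeltaMatrix


def _brute_force_bh(p):
    """Independent step-up oracle: min over j>=i of m*p_(j)/j, clipped."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank0, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank0, m)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestTTest:
    def test_identical_groups(self):
        assert ttest_equal_var([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_textbook_pooled_variance_example(self):
        t, p = ttest_equal_var([1, 2, 3, 4], [3, 4, 5, 6])
        assert t == pytest.approx(-2.1909, abs=1e-4)
        assert p == pytest.approx(0.0707, abs=1e-3)

    def test_agrees_with_scipy_cross_check(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(1, 2, size=rng.integers(2, 12))
            t, p = ttest_equal_var(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_swap_symmetry(self):
        a, b = [1.0, 5.0, 2.0], [4.0, 4.5, 9.0]
        t1, p1 = ttest_equal_var(a, b)
        t2, p2 = ttest_equal_var(b, a)
        assert t1 == -t2 and p1 == p2

    def test_degenerate_variance_unequal_means(self):
        t, p = ttest_equal_var([2.0, 2.0], [5.0, 5.0])
        assert np.isinf(t) and t < 0 and p == 0.0

    def test_group_too_small(self):
        with pytest.raises(ValueError, match=">= 2"):
            ttest_equal_var([1.0], [1.0, 2.0])


class TestBH:
    def test_hand_step_up_example(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_missing_p_stays_missing(self):
        out = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], _brute_force_bh([0.01, 0.5]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(deadline=None, max_examples=150)
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(bh_fdr(p), _brute_force_bh(p), atol=1e-12)


def _delta_from(arr, columns, platform="metabolites_liver", params=None):
    params = params or [f"p{i}" for i in range(arr.shape[0])]
    values = pd.DataFrame(arr, index=pd.Index(params, name="parameter_id"),
                          columns=columns)
    prov = pd.DataFrame(
        {"control_study_id": "S1", "control_time_h": 24.0, "n_controls": 3},
        index=pd.Index(columns, name="sample_id"),
    )
    return DeltaMatrix(platform=platform, values=values, provenance=prov)


class TestDiscovery:
    def test_increased_class_held_out(self):
        """Moving 'increased' samples around must not change the test."""
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(30)]
        classes = {c: "negative" for c in cols[:15]}
        classes.update({c: "positive" for c in cols[15:25]})
        classes.update({c: "increased" for c in cols[25:]})
        base = rng.normal(0, 0.5, (5, 30))
        base[:, 15:25] += 2.0
        wild = base.copy()
        wild[:, 25:] += 100.0  # perturb only the held-out class
        r1 = discover_markers(_delta_from(base, cols), classes)
        r2 = discover_markers(_delta_from(wild, cols), classes)
        assert [r.p_value for r in r1] == [r.p_value for r in r2]

    def test_per_platform_fdr_independent_of_other_platforms(
        self, default_analysis
    ):
        """Adjusting one platform alone reproduces the joint run's values."""
        _, _, deltas, classes = default_analysis
        joint = {
            p: discover_markers(deltas[p], classes) for p in deltas
        }
        for p in deltas:
            alone = discover_markers(deltas[p], classes)
            assert [r.fdr for r in alone] == [r.fdr for r in joint[p]]

    def test_no_positive_samples_warns_and_returns_empty(self, caplog):
        cols = ["a", "b", "c", "d"]
        classes = {c: "negative" for c in cols}
        delta = _delta_from(np.zeros((2, 4)), cols)
        with caplog.at_level("WARNING", logger="hepamark"):
            assert discover_markers(delta, classes) == []
        assert any("no positive" in r.message for r in caplog.records)

    def test_sparse_parameter_skipped(self, caplog):
        cols = [f"s{i}" for i in range(8)]
        classes = {c: ("positive" if i < 4 else "negative")
                   for i, c in enumerate(cols)}
        arr = np.random.default_rng(0).normal(size=(2, 8))
        arr[1, :3] = np.nan  # only one observed positive value
        with caplog.at_level("WARNING", logger="hepamark"):
            res = discover_markers(_delta_from(arr, cols), classes)
        assert [r.parameter_id for r in res] == ["p0"]
        assert any("skipped" in r.message for r in caplog.records)

    def test_significance_invariant_under_input_order(self, default_analysis):
        _, _, deltas, classes = default_analysis
        d = deltas["clinical_chemistry"]
        shuffled = DeltaMatrix(
            platform=d.platform,
            values=d.values.iloc[::-1, ::-1],
            provenance=d.provenance,
        )
        sig1 = {r.parameter_id for r in discover_markers(d, classes)
                if r.significant}
        sig2 = {r.parameter_id for r in discover_markers(shuffled, classes)
                if r.significant}
        assert sig1 == sig2

    def test_matches_scalar_ttest_path(self, default_analysis):
        """Vectorized discovery equals the scalar t-test on each parameter."""
        _, _, deltas, classes = default_analysis
        d = deltas["clinical_chemistry"]
        cls = classes["class"]
        res = {r.parameter_id: r for r in discover_markers(d, classes)}
        for pid, r in list(res.items())[:10]:
            pos = d.values.loc[pid, [s for s in d.values.columns
                                     if cls[s] == "positive"]]
            neg = d.values.loc[pid, [s for s in d.values.columns
                                     if cls[s] == "negative"]]
            t, p = ttest_equal_var(pos, neg)
            assert r.t_statistic == pytest.approx(t, rel=1e-9)
            assert r.p_value == pytest.approx(p, rel=1e-9)


class TestRanking:
    def test_fold_change_breaks_p_ties(self):
        a = hm.MarkerResult("big", "clinical_chemistry", 5, 0.001, 0.01,
                            2.9, 2 ** 2.9, 5, 5, True)
        b = hm.MarkerResult("small", "clinical_chemistry", 5, 0.001, 0.01,
                            2.2, 2 ** 2.2, 5, 5, True)
        ranked = rank_markers([b, a])
        assert [r.parameter_id for r in ranked] == ["big", "small"]
        assert ranked[0].rank == 1

    def test_single_result_rank_one(self):
        a = hm.MarkerResult("x", "clinical_chemistry", 1, 0.5, 0.5, 0.1,
                            2 ** 0.1, 5, 5, False)
        assert rank_markers([a])[0].rank == 1

    def test_permutation_invariance(self, default_analysis):
        _, _, deltas, classes = default_analysis
        res = discover_markers(deltas["transcripts_liver"], classes)
        r1 = rank_markers(res)
        r2 = rank_markers(list(reversed(res)))
        assert [r.parameter_id for r in r1] == [r.parameter_id for r in r2]


class TestClassProfile:
    def test_increased_lies_between_negative_and_positive(
        self, default_analysis
    ):
        """The intermediate position of the increased class on the selected
        markers is the geometry that validates the three-way partition."""
        _, truth, deltas, classes = default_analysis
        planted = truth.parameters[truth.parameters["planted"]]
        for platform in ("transcripts_liver", "metabolites_serum"):
            pids = list(planted.index[planted["platform"] == platform])
            prof = class_profile(deltas[platform], classes, pids)
            up = prof.means.loc[
                planted.loc[pids, "delta_log2_positive"] > 0
            ]
            neg = up["negative"].mean()
            inc = up["increased"].mean()
            pos = up["positive"].mean()
            assert neg < inc < pos

    def test_degenerate_single_class_centered_at_zero(self):
        cols = ["a", "b"]
        classes = {"a": "negative", "b": "negative"}
        prof = class_profile(_delta_from(np.zeros((3, 2)), cols), classes,
                             ["p0", "p1", "p2"])
        peak = prof.grid[np.argmax(prof.densities["negative"])]
        assert abs(peak) < 0.05

    def test_densities_integrate_to_one(self, default_analysis):
        _, truth, deltas, classes = default_analysis
        pids = list(truth.parameters.index[
            truth.parameters["planted"]
            & (truth.parameters["platform"] == "transcripts_liver")
        ])
        prof = class_profile(deltas["transcripts_liver"], classes, pids)
        for dens in prof.densities.values():
            assert np.trapezoid(dens, prof.grid) == pytest.approx(
                1.0, abs=1e-6
            )


class TestHeatmap:
    def test_rows_grouped_and_columns_ordered(self, default_analysis):
        study, _, deltas, classes = default_analysis
        selected = {}
        for p in deltas:
            sig = [r.parameter_id
                   for r in discover_markers(deltas[p], classes)
                   if r.significant]
            selected[p] = sig
        heat = heatmap_matrix(deltas, classes, selected, study.vehicle_ids)
        assert len(heat.values) == sum(len(v) for v in selected.values())
        # platform blocks appear in display order
        plat_seq = list(dict.fromkeys(heat.row_platforms))
        expected = [p for p in ("transcripts_liver", "metabolites_serum",
                                "metabolites_liver", "clinical_chemistry")
                    if selected.get(p)]
        assert plat_seq == expected
        # column class blocks are contiguous and ordered
        grp_seq = list(dict.fromkeys(heat.column_groups))
        order = ["control_negative", "treated_negative", "increased",
                 "positive"]
        assert grp_seq == [g for g in order if g in grp_seq]

    def test_no_increased_samples_gives_three_blocks(self):
        cols = ["v1", "t1", "t2", "p1"]
        classes = {"v1": "negative", "t1": "negative", "t2": "negative",
                   "p1": "positive"}
        delta = _delta_from(np.ones((2, 4)), cols)
        heat = heatmap_matrix({"metabolites_liver": delta}, classes,
                              {"metabolites_liver": ["p0", "p1"]}, {"v1"})
        assert set(heat.column_groups) == {"control_negative",
                                           "treated_negative", "positive"}

    def test_serialization_round_trip_preserves_order(self, tmp_path,
                                                      default_analysis):
        study, _, deltas, classes = default_analysis
        selected = {"clinical_chemistry": ["Bilirubin", "BA", "ALT"]}
        heat = heatmap_matrix(deltas, classes, selected, study.vehicle_ids)
        heat.to_tsv(tmp_path / "h.tsv")
        back = hm.HeatmapData.from_tsv(tmp_path / "h.tsv")
        assert list(back.values.index) == list(heat.values.index)
        assert list(back.values.columns) == list(heat.values.columns)
        assert list(back.column_groups) == list(heat.column_groups)
        np.testing.assert_allclose(back.values, heat.values, atol=1e-9)


class TestOutliers:
    def _frame(self, folds):
        """One negative sample with the given top-marker fold changes."""
        markers = [f"m{i}" for i in range(len(folds))]
        arr = np.array([[np.log2(f)] for f in folds])
        return _delta_from(arr, ["neg1"], params=markers), markers

    def test_worked_example_flagged(self):
        """A negative animal at 16x/16x/11x/3x on the top markers is the
        re-evaluate-histopathology signal."""
        delta, markers = self._frame([16.0, 16.0, 11.0, 3.0])
        flags = flag_outliers(delta, {"neg1": "negative"}, markers)
        assert len(flags) == 1
        assert len(flags[0].triggers) == 4
        folds = dict(flags[0].triggers)
        assert folds["m0"] == pytest.approx(16.0)

    def test_control_level_sample_not_flagged(self):
        delta, markers = self._frame([1.0, 1.1, 0.9, 1.05])
        assert flag_outliers(delta, {"neg1": "negative"}, markers) == []

    def test_boundary_k_minus_one_not_flagged(self):
        delta, markers = self._frame([4.0, 4.0, 1.0, 1.0])
        assert flag_outliers(delta, {"neg1": "negative"}, markers,
                             k_markers=3) == []
        delta2, markers2 = self._frame([4.0, 4.0, 4.0, 1.0])
        assert len(flag_outliers(delta2, {"neg1": "negative"}, markers2,
                                 k_markers=3)) == 1

    def test_only_negative_class_screened(self):
        delta, markers = self._frame([16.0, 16.0, 16.0])
        assert flag_outliers(delta, {"neg1": "positive"}, markers) == []
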