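import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histoquant.quantify import (
    RoiMeasurement,
    compare_groups,
    ddct_fold_change,
    intensity_fold_change,
    measure_roi,
    read_roi_polygons,
    significance_stars,
)


def _m(condition, value, channel="col1", background=0.0):
    return RoiMeasurement(image_id="img", channel=channel, condition=condition,
                          mean_intensity=value, background=background)


class TestIntensityFoldChange:
    def test_identical_values_fold_one(self):
        ms = [_m("old", 100.0), _m("old", 120.0), _m("pr", 100.0), _m("pr", 120.0)]
        out = intensity_fold_change(ms, "old")
        assert out.loc[out.condition == "pr", "fold_change"].mean() == pytest.approx(1.0)

    def test_doubled_values_fold_two(self):
        ms = [_m("old", 100.0), _m("old", 120.0), _m("pr", 200.0), _m("pr", 240.0)]
        out = intensity_fold_change(ms, "old")
        assert out.loc[out.condition == "pr", "fold_change"].mean() == pytest.approx(2.0)

    def test_hand_computed_example(self):
        # Reference {100, 120}, treated {330, 330}: 330 / 110 = 3.0.
        ms = [_m("old", 100.0), _m("old", 120.0), _m("pr", 330.0), _m("pr", 330.0)]
        out = intensity_fold_change(ms, "old")
        assert out.loc[out.condition == "pr", "fold_change"].mean() == pytest.approx(3.0)

    def test_reference_mean_fold_is_one_exactly(self):
        rng = np.random.default_rng(0)
        ms = []
        for ch in ("col1", "eln", "fn1"):
            for v in rng.uniform(50, 500, 5):
                ms.append(_m("old", float(v), channel=ch))
            for v in rng.uniform(50, 500, 4):
                ms.append(_m("pr", float(v), channel=ch))
        out = intensity_fold_change(ms, "old")
        for ch, grp in out.groupby("channel"):
            assert grp.loc[grp.condition == "old", "fold_change"].mean() == pytest.approx(1.0)

    def test_background_subtraction(self):
        ms = [_m("old", 110.0, background=10.0), _m("pr", 210.0, background=10.0)]
        out = intensity_fold_change(ms, "old")
        assert out.loc[out.condition == "pr", "fold_change"].iloc[0] == pytest.approx(2.0)

    def test_nonpositive_reference_error_names_channel(self):
        ms = [_m("old", 5.0, background=10.0, channel="eln"), _m("pr", 50.0, channel="eln")]
        with pytest.raises(ValueError, match="eln"):
            intensity_fold_change(ms, "old")

    def test_missing_reference_error(self):
        with pytest.raises(ValueError, match="reference"):
            intensity_fold_change([_m("pr", 100.0)], "old")


class TestRoi:
    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            RoiMeasurement("i", "c", "old", 1.0, roi=[[0, 0], [1, 1], [2, 2]])

    def test_measure_rectangle(self):
        img = np.zeros((100, 100))
        img[50:, :] = 200.0  # bottom half in row space = low y in Cartesian
        poly = np.array([[10.0, 5.0], [40.0, 5.0], [40.0, 20.0], [10.0, 20.0]])
        assert measure_roi(img, poly, pixel_size=1.0) == pytest.approx(200.0)

    def test_read_polygons_json_and_csv(self, tmp_path):
        import json

        jpath = tmp_path / "rois.json"
        jpath.write_text(json.dumps({"rois": [{"name": "wound",
                                               "vertices": [[0, 0], [10, 0], [10, 10]]}]}))
        rois = read_roi_polygons(jpath)
        assert rois["wound"].shape == (3, 2)

        cpath = tmp_path / "rois.csv"
        pd.DataFrame({"roi": ["a"] * 3, "x_um": [0, 5, 5], "y_um": [0, 0, 5]}).to_csv(
            cpath, index=False
        )
        rois = read_roi_polygons(cpath)
        assert rois["a"].shape == (3, 2)


class TestDdct:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(rows, columns=["sample", "condition", "ct_target", "ct_housekeeping"])

    def test_worked_example_fold_eight(self):
        df = self._records([("t1", "treated", 20.0, 18.0), ("r1", "reference", 23.0, 18.0)])
        out = ddct_fold_change(df)
        t = out[out.condition == "treated"].iloc[0]
        assert t.ddct == pytest.approx(-3.0)
        assert t.fold_change == pytest.approx(8.0)

    def test_equal_dct_fold_one(self):
        df = self._records([("t1", "treated", 21.0, 18.0), ("r1", "reference", 24.0, 21.0)])
        out = ddct_fold_change(df)
        assert out[out.condition == "treated"].fold_change.iloc[0] == pytest.approx(1.0)

    def test_ddct_minus_one_fold_two(self):
        df = self._records([("t1", "treated", 19.0, 18.0), ("r1", "reference", 20.0, 18.0)])
        out = ddct_fold_change(df)
        assert out[out.condition == "treated"].fold_change.iloc[0] == pytest.approx(2.0)

    def test_ct_offset_invariance(self):
        base = self._records(
            [("t1", "treated", 20.0, 18.0), ("t2", "treated", 21.5, 18.5),
             ("r1", "reference", 23.0, 18.0), ("r2", "reference", 22.0, 17.5)]
        )
        shifted = base.copy()
        shifted[["ct_target", "ct_housekeeping"]] += 4.0
        f1 = ddct_fold_change(base).fold_change
        f2 = ddct_fold_change(shifted).fold_change
        assert np.allclose(f1, f2)

    def test_missing_housekeeping_skipped(self, caplog):
        df = self._records(
            [("t1", "treated", 20.0, np.nan), ("t2", "treated", 20.0, 18.0),
             ("r1", "reference", 23.0, 18.0)]
        )
        with caplog.at_level(logging.WARNING):
            out = ddct_fold_change(df)
        assert len(out) == 2
        assert "skipping" in caplog.text

    def test_ct_out_of_range(self):
        df = self._records([("t1", "treated", 50.0, 18.0), ("r1", "reference", 23.0, 18.0)])
        with pytest.raises(ValueError, match="0, 45"):
            ddct_fold_change(df)

    def test_per_gene_grouping(self):
        df = pd.DataFrame(
            {
                "sample": ["t", "r", "t", "r"],
                "condition": ["treated", "reference"] * 2,
                "gene": ["a", "a", "b", "b"],
                "ct_target": [20.0, 23.0, 25.0, 25.0],
                "ct_housekeeping": [18.0] * 4,
            }
        )
        out = ddct_fold_change(df)
        folds = out[out.condition == "treated"].set_index("gene").fold_change
        assert folds["a"] == pytest.approx(8.0)
        assert folds["b"] == pytest.approx(1.0)


class TestCompareGroups:
    def test_identical_groups_paired_t(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        out = compare_groups(g, "paired_t")
        assert out.statistic.iloc[0] == 0.0
        assert out.pvalue.iloc[0] == 1.0

    def test_mann_whitney_complete_separation(self):
        g = {"lo": list(range(1, 11)), "hi": list(range(11, 21))}
        out = compare_groups(g, "mann_whitney")
        assert out.statistic.iloc[0] == 0.0

    def test_mann_whitney_matches_exact_enumeration(self):
        # Independent oracle: exact permutation distribution of U at n = 4 + 4.
        x = [1.2, 3.4, 2.2, 5.0]
        y = [2.9, 6.1, 4.4, 7.0]
        out = compare_groups({"x": x, "y": y}, "mann_whitney")
        pooled = np.array(x + y)
        u_obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
            1 for xi in x for yi in y if xi == yi
        )
        n1 = len(x)
        us = []
        for comb in itertools.combinations(range(8), n1):
            xs = pooled[list(comb)]
            ys = pooled[[i for i in range(8) if i not in comb]]
            u = sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
                1 for a in xs for b in ys if a == b
            )
            us.append(u)
        us = np.array(us)
        mu = n1 * (8 - n1) / 2
        p_exact = np.mean(np.abs(us - mu) >= abs(u_obs - mu))
        assert out.pvalue.iloc[0] == pytest.approx(p_exact, abs=1e-6)

    def test_paired_t_matches_closed_form(self):
        x = np.array([4.1, 5.2, 6.3, 5.9, 4.8, 5.5])
        y = np.array([3.9, 5.0, 6.8, 5.1, 4.2, 5.9])
        out = compare_groups({"x": x, "y": y}, "paired_t")
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert out.statistic.iloc[0] == pytest.approx(t, abs=1e-9)
        assert out.pvalue.iloc[0] == pytest.approx(p, abs=1e-6)

    def test_anova_and_tukey(self):
        rng = np.random.default_rng(0)
        g = {k: rng.normal(loc, 1.0, 20) for k, loc in (("a", 0.0), ("b", 0.1), ("c", 2.0))}
        anova = compare_groups(g, "anova")
        assert anova.pvalue.iloc[0] < 0.001
        tukey = compare_groups(g, "tukey_hsd")
        assert len(tukey) == 3
        p = tukey.set_index("comparison").pvalue
        assert p["a vs c"] < 0.001
        assert p["a vs b"] > 0.05

    def test_unequal_paired_lengths(self):
        with pytest.raises(ValueError, match="equal-length"):
            compare_groups({"a": [1, 2, 3], "b": [1, 2]}, "paired_t")

    def test_small_n_flagged_unreliable(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = compare_groups({"a": [1.0, 2.0], "b": [3.0, 4.0]}, "mann_whitney")
        assert not out.reliable.iloc[0]
        assert len(out) == 1

    def test_unknown_test(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1], "b": [2]}, "wilcoxon")

    def test_type_i_error_quick(self):
        rng = np.random.default_rng(1)
        rejections = 0
        reps = 200
        for _ in range(reps):
            a, b = rng.normal(size=30), rng.normal(size=30)
            p = compare_groups({"a": a, "b": b}, "mann_whitney").pvalue.iloc[0]
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_stars(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == "ns"
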