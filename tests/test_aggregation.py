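"""Score scaling, median smoothing, slide decisions, ROC and heatmaps."""

import numpy as np
import pytest

from wsimet import aggregation as agg


def make_grid(scores, valid=None):
    scores = np.asarray(scores, dtype=float)
    if valid is None:
        valid = np.ones_like(scores, dtype=bool)
    return agg.ScoreGrid("g", scores, valid)


class TestShiftScale:
    @pytest.mark.parametrize("p,s", [(0.5, 0.0), (1.0, 50.0), (0.0, -50.0),
                                     (0.75, 25.0)])
    def test_affine_map(self, p, s):
        assert agg.shift_scale(p) == pytest.approx(s)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            agg.shift_scale(1.2)

    def test_roundtrip_exact(self, rng):
        p = rng.random(1000)
        np.testing.assert_array_almost_equal(
            agg.inverse_shift_scale(agg.shift_scale(p)), p, decimal=14)


class TestMedianSmooth:
    def test_constant_grid_unchanged(self):
        grid = make_grid(np.full((4, 5), 7.0))
        out = agg.median_smooth(grid)
        np.testing.assert_array_equal(out.scores, grid.scores)

    def test_two_by_two_hand_enumeration(self):
        # forward windows with border clipping:
        # (0,0) sees the whole grid -> median 25; (0,1) sees {20,40} -> 30;
        # (1,0) sees {30,40} -> 35; (1,1) sees only itself -> 40
        out = agg.median_smooth(make_grid([[10.0, 20.0], [30.0, 40.0]]))
        np.testing.assert_allclose(out.scores, [[25.0, 30.0], [35.0, 40.0]])

    def test_three_by_three_hand_enumeration(self):
        g = [[1.0, 2.0, 3.0],
             [4.0, 5.0, 6.0],
             [7.0, 8.0, 9.0]]
        # interior (0,0): {1,2,4,5} -> 3; right edge (0,2): {3,6} -> 4.5;
        # bottom edge (2,0): {7,8} -> 7.5; corner (2,2): {9} -> 9
        out = agg.median_smooth(make_grid(g))
        expected = [[3.0, 4.0, 4.5], [6.0, 7.0, 7.5], [7.5, 8.5, 9.0]]
        np.testing.assert_allclose(out.scores, expected)

    def test_invalid_cells_excluded_and_kept(self):
        valid = np.array([[True, False], [True, True]])
        grid = make_grid([[10.0, -99.0], [30.0, 40.0]], valid)
        out = agg.median_smooth(grid)
        # (0,0) window holds valid {10,30,40} -> 30; invalid cell untouched
        assert out.scores[0, 0] == pytest.approx(30.0)
        assert out.scores[0, 1] == -99.0
        np.testing.assert_array_equal(out.valid, valid)

    def test_negation_symmetry(self, rng):
        # median of the negated set equals the negated median under the
        # even-count mean rule, so smoothing commutes with global negation
        for _ in range(100):
            shape = (int(rng.integers(2, 7)), int(rng.integers(2, 7)))
            scores = rng.uniform(-50, 50, size=shape)
            valid = rng.random(shape) < 0.8
            grid = make_grid(scores, valid)
            neg = make_grid(-scores, valid)
            out = agg.median_smooth(grid).scores
            out_neg = agg.median_smooth(neg).scores
            np.testing.assert_allclose(out[valid], -out_neg[valid])

    def test_output_within_input_range(self, rng):
        scores = rng.uniform(-50, 50, size=(6, 6))
        out = agg.median_smooth(make_grid(scores))
        assert out.scores.min() >= scores.min() - 1e-12
        assert out.scores.max() <= scores.max() + 1e-12

    def test_idempotent_on_constant(self):
        grid = make_grid(np.full((3, 3), -12.5))
        once = agg.median_smooth(grid)
        twice = agg.median_smooth(once)
        np.testing.assert_array_equal(once.scores, twice.scores)


class TestSlideScore:
    def test_high_probability_slide(self):
        grid = make_grid(np.full((2, 2), agg.shift_scale(0.9)))
        d = agg.slide_score(grid, true_label="met")
        assert d.mean_score == pytest.approx(40.0)
        assert d.predicted_label == "met"

    def test_tie_called_non_metastatic(self):
        d = agg.slide_score(make_grid([[10.0, -10.0], [10.0, -10.0]]))
        assert d.mean_score == pytest.approx(0.0)
        assert d.predicted_label == "non_met"

    def test_mean_rule_beats_tile_majority(self):
        # 2 tiles at +30, 2 at -50: mean -10 -> non_met even though the
        # positive tiles match the negatives in count; documents that the
        # slide vote is the sign of the mean score
        d = agg.slide_score(make_grid([[30.0, -50.0], [-50.0, 30.0]]))
        assert d.mean_score == pytest.approx(-10.0)
        assert d.predicted_label == "non_met"

    def test_count_vote_alternative(self):
        grid = make_grid([[30.0, 30.0], [30.0, -50.0]])
        assert agg.slide_score(grid, vote="count").predicted_label == "met"

    def test_no_valid_cells_rejected(self):
        grid = make_grid([[1.0]], np.array([[False]]))
        with pytest.raises(ValueError):
            agg.slide_score(grid)


class TestRocCurve:
    def test_perfect_separation(self):
        *_, auc = agg.roc_curve([1, 2, 10, 11], [False, False, True, True])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        *_, auc = agg.roc_curve([5, 5, 5, 5], [True, False, True, False])
        assert auc == 0.5

    def test_four_point_hand_case(self):
        # pairs (case, control): (4,3) and (4,1) concordant, (2,3)
        # discordant, (2,1) concordant -> 3/4
        *_, auc = agg.roc_curve([4, 2, 3, 1], [True, True, False, False])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            agg.roc_curve([1, 2], [True, True])

    def test_matches_pairwise_concordance_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            *_, auc = agg.roc_curve(scores, labels)
            cases, controls = scores[labels], scores[~labels]
            conc = sum(1.0 if a > b else (0.5 if a == b else 0.0)
                       for a in cases for b in controls)
            assert auc == pytest.approx(conc / (len(cases) * len(controls)),
                                        abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        *_, auc = agg.roc_curve(scores, labels)
        *_, auc2 = agg.roc_curve(np.exp(3 * scores), labels)
        assert auc == pytest.approx(auc2, abs=1e-12)


class TestConfusionSummary:
    def test_published_slide_counts(self):
        # rapid cohort: 14 predicted met / 8 non-met; non-metastatic
        # cohort: 14 predicted met / 45 non-met
        out = agg.confusion_summary(counts={"tp": 14, "fn": 8, "tn": 45, "fp": 14})
        assert round(out["sensitivity"]) == 64
        assert round(out["specificity"]) == 76
        assert round(out["accuracy"]) == 73

    def test_all_correct(self):
        out = agg.confusion_summary(counts={"tp": 5, "fn": 0, "tn": 7, "fp": 0})
        assert out == {"sensitivity": 100.0, "specificity": 100.0,
                       "accuracy": 100.0}

    def test_inversion_complement(self):
        orig = agg.confusion_summary(counts={"tp": 14, "fn": 8, "tn": 45, "fp": 14})
        inv = agg.confusion_summary(counts={"tp": 8, "fn": 14, "tn": 14, "fp": 45})
        assert inv["sensitivity"] == pytest.approx(100 - orig["sensitivity"])
        assert inv["specificity"] == pytest.approx(100 - orig["specificity"])

    def test_from_decisions(self):
        decisions = [
            agg.SlideDecision("a", 10.0, "met", "met"),
            agg.SlideDecision("b", -5.0, "non_met", "met"),
            agg.SlideDecision("c", -1.0, "non_met", "non_met"),
        ]
        out = agg.confusion_summary(decisions)
        assert out["sensitivity"] == pytest.approx(50.0)
        assert out["specificity"] == pytest.approx(100.0)


class TestProbabilityMap:
    def test_zero_grid_uniform_midpoint(self):
        img = agg.render_probability_map(make_grid(np.zeros((2, 2))), tile_px=4)
        assert len(np.unique(img.reshape(-1, 3), axis=0)) == 1

    def test_single_hot_tile_is_red(self):
        valid = np.zeros((2, 2), dtype=bool)
        valid[0, 0] = True
        scores = np.zeros((2, 2))
        scores[0, 0] = 50.0
        img = agg.render_probability_map(make_grid(scores, valid), tile_px=4)
        r, g, b = img[0, 0]
        assert r == 255 and b < 60          # saturated red tile
        assert (img[4:, 4:] == 255).all()   # everything else white

    def test_palette_monotone_in_score(self):
        # higher score -> redder (red-blue channel difference increases)
        scores = np.linspace(-50, 50, 11)[None, :]
        img = agg.render_probability_map(
            make_grid(scores, np.ones_like(scores, bool)), tile_px=1)
        diff = img[0, :, 0].astype(int) - img[0, :, 2].astype(int)
        assert (np.diff(diff) >= 0).all()
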