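"""Spot-box quantification, background correction, and significance tests."""

import numpy as np
import pandas as pd
import pytest
from oracles import (
    anova_F_oracle,
    enumerate_background_boxes,
    ttest_oracle,
    tukey_p_oracle,
)

from hcscreen import (
    anova_tukey,
    condition_summary,
    corrected_intensity,
    estimate_background,
    measure_spots,
    render_metaphase_spread,
    spot_max_in_box,
    two_sample_ttest,
)


class TestSpotMax:
    def test_flat_image_returns_its_value(self):
        img = np.full((32, 32), 123.0)
        assert spot_max_in_box(img, (16, 16)) == 123.0

    def test_gaussian_spot_peak_recovered(self):
        img, truth, _ = render_metaphase_spread(5, 400.0, background=100.0, seed=2)
        for rec in truth.itertuples():
            assert spot_max_in_box(img, (rec.row, rec.col)) == pytest.approx(500.0)

    def test_off_center_still_captures_narrow_peak(self):
        img, truth, _ = render_metaphase_spread(5, 400.0, background=100.0, spot_sigma=2.0, seed=2)
        rec = truth.iloc[0]
        assert spot_max_in_box(img, (rec.row + 3, rec.col + 3)) == pytest.approx(500.0)

    def test_clipped_box_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            spot_max_in_box(img, (1, 16))


class TestBackground:
    def test_flat_background_exact(self):
        img = np.full((64, 64), 77.0)
        mask = np.ones_like(img, dtype=bool)
        assert estimate_background(img, mask, seed=1) == 77.0

    def test_seeded_placement_reproducible(self, rng):
        img = rng.normal(100, 10, (64, 64))
        mask = np.ones_like(img, dtype=bool)
        assert estimate_background(img, mask, seed=5) == estimate_background(img, mask, seed=5)
        assert estimate_background(img, mask, seed=5) != estimate_background(img, mask, seed=6)

    def test_noisy_background_within_oracle_distribution(self, rng):
        img = rng.normal(100, 8, (48, 48))
        mask = np.ones_like(img, dtype=bool)
        maxima = enumerate_background_boxes(img, mask)
        est = estimate_background(img, mask, seed=3)
        # estimate averages 4 box maxima; compare against the population of
        # all admissible box maxima
        assert abs(est - maxima.mean()) <= 3.0 * maxima.std()

    def test_mask_too_small_rejected(self):
        img = np.zeros((20, 20))
        mask = np.zeros_like(img, dtype=bool)
        mask[:8, :8] = True  # room for exactly one box
        with pytest.raises(ValueError):
            estimate_background(img, mask, n_boxes=4)


class TestCorrected:
    @pytest.mark.parametrize("raw, bg, expected", [(500.0, 100.0, 400.0), (80.0, 80.0, 0.0)])
    def test_subtraction(self, raw, bg, expected):
        assert corrected_intensity(raw, bg) == expected

    def test_translation_invariance(self):
        img, truth, mask = render_metaphase_spread(10, 400.0, background=100.0, noise_sd=5.0, seed=7)
        spots = truth.rename(columns={"spot_id": "cell_id"})[["cell_id", "row", "col", "spot_class"]]
        spots["cell_id"] = 0
        a = measure_spots(img, spots, mask, seed=9)
        b = measure_spots(img + 250.0, spots, mask, seed=9)
        assert np.allclose(a.corrected, b.corrected, atol=1e-9)

    def test_rendered_spots_recover_amplitude(self):
        img, truth, mask = render_metaphase_spread(
            100, 400.0, background=100.0, noise_sd=8.0, image_shape=(1024, 1024), seed=4
        )
        spots = truth[["row", "col", "spot_class"]].copy()
        out = measure_spots(img, spots, mask, seed=4)
        assert out.corrected.mean() == pytest.approx(400.0, rel=0.05)


class TestConditionSummary:
    def test_closed_form_mean_sem(self):
        s = condition_summary([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.sem == pytest.approx(1.0 / np.sqrt(3.0))

    def test_self_reference_fold_change_is_one(self):
        s = condition_summary([4.0, 5.0], reference_values=[4.0, 5.0])
        assert s.fold_change_vs_reference == pytest.approx(1.0)

    def test_sem_scales_inverse_sqrt_n(self, rng):
        base = rng.normal(10, 2, 50)
        s1 = condition_summary(base)
        s4 = condition_summary(np.tile(base, 4))
        assert s4.sem == pytest.approx(s1.sem / 2.0, rel=0.02)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            condition_summary([1.0, 2.0], reference_values=[-1.0, 1.0])


class TestSignificance:
    def test_identical_groups_ttest_null(self):
        t, df, p = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_ttest_matches_closed_form_oracle(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        t, df, p = two_sample_ttest(a, b)
        t0, df0, p0 = ttest_oracle(a, b)
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == df0
        assert p == pytest.approx(p0, abs=1e-10)

    def test_welch_differs_under_unequal_variance(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [10.0, 30.0, 50.0]
        _, df_student, _ = two_sample_ttest(a, b, equal_var=True)
        _, df_welch, _ = two_sample_ttest(a, b, equal_var=False)
        assert df_welch < df_student

    def test_identical_groups_anova_null(self):
        g = [1.0, 2.0, 1.0]
        F, p, pairwise = anova_tukey([g, g, g])
        assert F == 0.0 and p == 1.0
        assert (pairwise.p_adj == 1.0).all()

    def test_anova_matches_sums_of_squares_oracle(self):
        groups = [[1.0, 2.0, 3.0], [1.5, 2.5, 3.5], [6.0, 7.0, 8.0]]
        F, p, _ = anova_tukey(groups)
        F0, p0 = anova_F_oracle(groups)
        assert F == pytest.approx(F0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_tukey_matches_studentized_range_oracle(self):
        groups = [[1.0, 2.0, 3.0], [1.5, 2.5, 3.5], [6.0, 7.0, 8.0]]
        _, _, pairwise = anova_tukey(groups)
        for row in pairwise.itertuples():
            i = int(row.group_a[-1]) - 1
            j = int(row.group_b[-1]) - 1
            assert row.p_adj == pytest.approx(tukey_p_oracle(groups, i, j), abs=1e-10)

    def test_tukey_adjusted_p_conservative(self, rng):
        groups = [rng.normal(m, 1.0, 6) for m in (0.0, 0.5, 1.5)]
        _, _, pairwise = anova_tukey(groups, labels=["a", "b", "c"])
        idx = {"a": 0, "b": 1, "c": 2}
        for row in pairwise.itertuples():
            _, _, p_raw = two_sample_ttest(groups[idx[row.group_a]], groups[idx[row.group_b]])
            assert row.p_adj >= p_raw - 1e-12

    def test_group_size_preconditions(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            anova_tukey([[1.0, 2.0], [3.0, 4.0]])
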