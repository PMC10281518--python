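"""B-score normalization, robust Z-scoring, and gene-level aggregation."""

import numpy as np
import pandas as pd
import pytest
from oracles import medpolish_residuals_oracle, robust_z_oracle

from hcscreen import (
    PlateMatrix,
    ScreenDesign,
    TruthModel,
    bscore_plate,
    build_screen_layout,
    call_hits,
    gene_scores,
    median_polish,
    score_screen,
    simulate_well_values,
    sirna_scores,
    zscore_replicate,
)
from hcscreen.screen_stats import plate_matrices, robust_z


class TestMedianPolish:
    def test_exactly_additive_grid_has_zero_residuals(self):
        fit = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.abs(fit.residuals).max() < 1e-12

    def test_constant_grid(self):
        fit = median_polish(np.full((4, 5), 7.5))
        assert fit.overall == pytest.approx(7.5)
        assert np.abs(fit.row_effects).max() < 1e-12
        assert np.abs(fit.col_effects).max() < 1e-12
        assert np.abs(fit.residuals).max() < 1e-12

    def test_outlier_grid_matches_sweep_oracle(self):
        g = np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 100]])
        fit = median_polish(g, max_iter=200, tol=1e-12)
        oracle = medpolish_residuals_oracle(g)
        assert np.abs(fit.residuals - oracle).max() < 1e-9

    def test_random_grids_with_missing_match_oracle(self, rng):
        for _ in range(20):
            g = rng.normal(100, 25, (8, 12))
            g[rng.random(g.shape) < 0.1] = np.nan
            fit = median_polish(g, max_iter=800, tol=0.0)
            oracle = medpolish_residuals_oracle(g)
            both = np.isfinite(fit.residuals) & np.isfinite(oracle)
            assert np.array_equal(np.isnan(fit.residuals), np.isnan(oracle))
            assert np.abs(fit.residuals[both] - oracle[both]).max() < 1e-9

    def test_reconstruction_identity(self, rng):
        g = rng.normal(0, 10, (6, 9))
        fit = median_polish(g, max_iter=500, tol=1e-13)
        recon = fit.overall + fit.row_effects[:, None] + fit.col_effects[None, :] + fit.residuals
        assert np.abs(recon - g).max() < 1e-9

    def test_all_missing_column_warns_and_keeps_zero_effect(self):
        g = np.array([[1.0, np.nan, 2], [3, np.nan, 4], [5, np.nan, 6]])
        with pytest.warns(UserWarning):
            fit = median_polish(g)
        assert fit.col_effects[1] == 0.0

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            median_polish(np.array([[1.0, 2.0]]))


def _plate_from_values(values, lib_mask=None):
    values = np.asarray(values, dtype=float)
    if lib_mask is None:
        lib_mask = np.ones_like(values, dtype=bool)
    return PlateMatrix("P01", 1, values, lib_mask)


class TestBScore:
    def test_exactly_additive_plate_is_degenerate_all_zero(self, rng):
        rowe = rng.normal(0, 50, 8)
        cole = rng.normal(0, 30, 10)
        values = 1000 + rowe[:, None] + cole[None, :]
        res = bscore_plate(_plate_from_values(values))
        assert res.degenerate
        assert np.abs(res.bscores).max() == 0.0

    def test_location_and_scale_equivariance(self, rng):
        values = rng.normal(1000, 20, (8, 10))
        base = bscore_plate(_plate_from_values(values)).bscores
        shifted = bscore_plate(_plate_from_values(values + 123.0)).bscores
        scaled = bscore_plate(_plate_from_values(values * 4.2)).bscores
        assert np.allclose(base, shifted, atol=1e-9)
        assert np.allclose(base, scaled, atol=1e-9)

    def test_library_bscore_mad_is_unit(self, rng):
        values = rng.normal(1000, 20, (16, 24))
        res = bscore_plate(_plate_from_values(values))
        lib = res.bscores[np.isfinite(res.bscores)]
        mad = 1.4826 * np.median(np.abs(lib - np.median(lib)))
        assert mad == pytest.approx(1.0, abs=1e-12)

    def test_control_wells_do_not_shift_library_scores(self, rng):
        values = rng.normal(1000, 15, (8, 10))
        lib_mask = np.ones((8, 10), dtype=bool)
        lib_mask[:, -2:] = False  # last two columns are controls
        base = bscore_plate(PlateMatrix("P01", 1, values.copy(), lib_mask))
        spiked = values.copy()
        spiked[:, -2:] += 10000.0
        after = bscore_plate(PlateMatrix("P01", 1, spiked, lib_mask))
        assert np.array_equal(base.bscores[lib_mask], after.bscores[lib_mask])

    def test_too_few_library_wells_rejected(self, rng):
        values = rng.normal(0, 1, (4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :3] = True
        with pytest.raises(ValueError):
            bscore_plate(PlateMatrix("P01", 1, values, mask))


class TestZScore:
    def test_library_median_scores_zero(self, rng):
        values = rng.normal(0, 1, (8, 10))
        lib = np.ones_like(values, dtype=bool)
        z, _ = zscore_replicate([(_plate_from_values(values), values)])
        med = np.median(values)
        idx = np.unravel_index(np.argmin(np.abs(values - med)), values.shape)
        assert abs(z[0][idx]) == pytest.approx(
            abs(values[idx] - med) / (1.4826 * np.median(np.abs(values - med))), abs=1e-12
        )

    def test_matches_median_mad_oracle(self):
        values = np.array([[1.0, 2.0, 3.0], [4.0, 100.0, np.nan]])
        pm = _plate_from_values(values)
        z, info = zscore_replicate([(pm, values)], min_library=5)
        expected = robust_z_oracle(100.0, [1, 2, 3, 4, 100])
        assert z[0][1, 1] == pytest.approx(expected, abs=1e-12)
        assert not info["degenerate"]

    def test_shift_invariance(self, rng):
        values = rng.normal(5, 2, (6, 8))
        pm = _plate_from_values(values)
        z1, _ = zscore_replicate([(pm, values)])
        pm2 = _plate_from_values(values + 77.0)
        z2, _ = zscore_replicate([(pm2, values + 77.0)])
        assert np.allclose(z1[0], z2[0], atol=1e-9)

    def test_degenerate_scale_flags_and_zeroes(self):
        values = np.full((4, 4), 3.0)
        z, info = zscore_replicate([(_plate_from_values(values), values)])
        assert info["degenerate"]
        assert np.abs(z[0]).max() == 0.0

    def test_classical_method_option(self, rng):
        values = rng.normal(0, 1, (6, 8))
        pm = _plate_from_values(values)
        z, _ = zscore_replicate([(pm, values)], method="classical")
        expected = (values - values.mean()) / values.std(ddof=1)
        assert np.allclose(z[0], expected, atol=1e-12)

    def test_unknown_method_rejected(self, rng):
        values = rng.normal(0, 1, (4, 4))
        with pytest.raises(ValueError):
            zscore_replicate([(_plate_from_values(values), values)], method="mean")


class TestAggregation:
    def test_sirna_mean_over_replicates(self):
        ws = pd.DataFrame(
            {"sirna_id": ["a", "a"], "gene_id": ["g", "g"], "replicate": [1, 2],
             "z": [2.0, 4.0]}
        )
        out = sirna_scores(ws)
        assert out.sirna_level_z.iloc[0] == pytest.approx(3.0)
        assert out.n_replicates.iloc[0] == 2

    def test_missing_replicate_falls_back_to_available(self):
        ws = pd.DataFrame(
            {"sirna_id": ["a", "a"], "gene_id": ["g", "g"], "replicate": [1, 2],
             "z": [2.5, np.nan]}
        )
        out = sirna_scores(ws)
        assert out.sirna_level_z.iloc[0] == pytest.approx(2.5)
        assert out.n_replicates.iloc[0] == 1

    def test_replicate_order_irrelevant(self):
        a = pd.DataFrame({"sirna_id": ["a"] * 2, "gene_id": ["g"] * 2,
                          "replicate": [1, 2], "z": [1.0, 5.0]})
        b = a.iloc[::-1].reset_index(drop=True)
        assert sirna_scores(a).sirna_level_z.iloc[0] == sirna_scores(b).sirna_level_z.iloc[0]

    @pytest.mark.parametrize(
        "zs, expected",
        [([5.0, 3.0, 1.0], 3.0), ([8.0, 0.1, -0.2], 0.1), ([2.0, 4.0], 3.0)],
    )
    def test_gene_median_is_second_strongest(self, zs, expected):
        tab = pd.DataFrame(
            {"sirna_id": [f"s{i}" for i in range(len(zs))],
             "gene_id": ["g"] * len(zs), "sirna_level_z": zs,
             "n_replicates": [2] * len(zs)}
        )
        out = gene_scores(tab)
        assert out.gene_median_z.iloc[0] == pytest.approx(expected)

    def test_ranking_descending_with_lexicographic_ties(self):
        tab = pd.DataFrame(
            {"sirna_id": ["s1", "s2", "s3"],
             "gene_id": ["gB", "gA", "gC"],
             "sirna_level_z": [1.0, 1.0, 5.0],
             "n_replicates": [2] * 3}
        )
        out = gene_scores(tab)
        assert list(out.gene_id) == ["gC", "gA", "gB"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_call_hits_extremes(self):
        tab = gene_scores(pd.DataFrame(
            {"sirna_id": list("abc"), "gene_id": list("xyz"),
             "sirna_level_z": [1.0, 2.0, 3.0], "n_replicates": [2] * 3}
        ))
        assert call_hits(tab, np.inf).hit.sum() == 0
        assert call_hits(tab, -np.inf).hit.sum() == 3


class TestEndToEnd:
    def test_separated_spiked_effects_ranked_in_true_order(self):
        """Scattered genes spiked with widely separated effects (40x the
        noise floor apart) come out in exactly the true effect order at the
        top of the ranking."""
        design = ScreenDesign(n_genes=117, n_replicates=2)
        layouts = build_screen_layout(design)
        spiked = {f"G{i:04d}": float(20 * k) for k, i in enumerate([5, 20, 35, 50, 65, 80, 95, 110], start=1)}
        potency = {sid: 1.0 for g in spiked for sid in design.sirna_ids(g)}
        truth = TruthModel(noise_sd=0.5, gene_effect=spiked, sirna_potency=potency)
        tab = simulate_well_values(layouts, truth, design, seed=2)
        scores = score_screen(tab, layouts)
        top = list(scores.gene_scores.gene_id.head(len(spiked)))
        true_order = sorted(spiked, key=lambda g: -spiked[g])
        assert top == true_order

    def test_missing_wells_propagate(self, small_design, small_layouts):
        truth = TruthModel(noise_sd=5.0)
        tab = simulate_well_values(small_layouts, truth, small_design, seed=4)
        tab.loc[
            (tab.sirna_id == "G0001.s1") & (tab.replicate == 1), "raw_value"
        ] = np.nan
        scores = score_screen(tab, small_layouts)
        row = scores.sirna_scores.set_index("sirna_id").loc["G0001.s1"]
        assert row.n_replicates == 1
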