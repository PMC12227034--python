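"""FDM accumulation, smoothing, z-scoring, marginal maps and similarity."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import stats

from gazemark.density_maps import (
    DegenerateMapError,
    DensityMap,
    FdmSpec,
    StageError,
    accumulate_fdm,
    category_fdms,
    cross_condition_similarity,
    map_correlation,
    marginal_maps,
    refixation_map,
    similarity_contrast,
    smooth_map,
    zscore_map,
)
from gazemark.synthetic_scanpaths import (
    default_config,
    generate_dataset,
    spotlight_divergent_config,
)

from .conftest import make_fixations, make_trials


def _centered_trial(pid="P01", tid="T001", emotion="anger", condition="unrestricted",
                    response=None):
    return (pid, tid, emotion, condition, 1, 512.0, 384.0, response or emotion, 4.0)


class TestAccumulate:
    def test_single_fixation_floor_binned(self, geom):
        # image frame (10.4, 20.9) corresponds to screen (330.4, 116.9)
        fix = make_fixations([("P01", "T001", 1, 330.4, 116.9, 200.0, 0.0)])
        trials = make_trials([_centered_trial()])
        m = accumulate_fdm(fix, trials, geom)
        assert m.grid[20, 10] == 200.0
        assert m.grid.sum() == 200.0
        assert m.total_mass == 200.0
        assert m.stage == "raw"

    def test_same_cell_additivity(self, geom):
        fix = make_fixations(
            [
                ("P01", "T001", 1, 330.4, 116.9, 200.0, 0.0),
                ("P01", "T001", 2, 330.9, 116.1, 250.0, 0.0),
            ]
        )
        trials = make_trials([_centered_trial()])
        m = accumulate_fdm(fix, trials, geom)
        assert m.grid[20, 10] == 450.0

    def test_total_mass_matches_brute_force(self, geom, rng):
        xy = rng.uniform(-100, 1100, size=(200, 2))
        dur = rng.uniform(100, 400, size=200)
        fix = make_fixations(
            [("P01", "T001", i + 1, x, y, d, 0.0) for i, ((x, y), d) in enumerate(zip(xy, dur))]
        )
        trials = make_trials([_centered_trial()])
        m = accumulate_fdm(fix, trials, geom)
        xi, yi = xy[:, 0] - (512 - 192), xy[:, 1] - (384 - 288)
        inb = (xi >= 0) & (xi < 384) & (yi >= 0) & (yi < 576)
        assert m.total_mass == pytest.approx(dur[inb].sum())
        assert m.n_out_of_bounds == int((~inb).sum())
        assert m.grid.sum() == pytest.approx(dur[inb].sum())

    def test_empty_input_gives_zero_map(self, geom):
        fix = make_fixations([])
        trials = make_trials([_centered_trial()])
        m = accumulate_fdm(fix, trials, geom)
        assert m.n_fixations == 0
        assert m.grid.sum() == 0.0


class TestSmooth:
    def test_delta_peak_matches_gaussian_closed_form(self):
        grid = np.zeros((576, 384))
        grid[288, 192] = 1000.0
        m = DensityMap(grid=grid, stage="raw")
        sm = smooth_map(m, sigma_px=13.0)
        peak = sm.grid[288, 192]
        assert peak == pytest.approx(1000.0 / (2 * np.pi * 13.0**2), rel=1e-3)
        # radial symmetry up to grid discretisation
        assert sm.grid[288 + 20, 192] == pytest.approx(sm.grid[288 - 20, 192], rel=1e-9)
        assert sm.grid[288, 192 + 20] == pytest.approx(sm.grid[288 + 20, 192], rel=1e-9)

    def test_interior_mass_preserved(self):
        grid = np.zeros((576, 384))
        grid[288, 192] = 777.0  # >= 4 sigma from every edge
        sm = smooth_map(DensityMap(grid=grid, stage="raw"), sigma_px=13.0)
        assert sm.grid.sum() == pytest.approx(777.0, rel=1e-6)

    def test_linearity(self, rng):
        a = np.zeros((100, 80))
        b = np.zeros((100, 80))
        a[30, 40] = 5.0
        b[60, 20] = 3.0
        sa = smooth_map(DensityMap(grid=a, stage="raw"), 4.0).grid
        sb = smooth_map(DensityMap(grid=b, stage="raw"), 4.0).grid
        sab = smooth_map(DensityMap(grid=a + b, stage="raw"), 4.0).grid
        np.testing.assert_allclose(sab, sa + sb, atol=1e-12)

    def test_tiny_sigma_is_near_identity(self, rng):
        grid = rng.uniform(0, 1, size=(50, 40))
        sm = smooth_map(DensityMap(grid=grid, stage="raw"), sigma_px=1e-3)
        np.testing.assert_allclose(sm.grid, grid, atol=1e-9)

    def test_nonpositive_sigma_rejected(self):
        m = DensityMap(grid=np.zeros((10, 10)), stage="raw")
        with pytest.raises(ValueError):
            smooth_map(m, 0.0)


class TestZscore:
    def test_mean_zero_sd_one(self, rng):
        grid = rng.uniform(0, 5, size=(60, 40))
        z = zscore_map(DensityMap(grid=grid, stage="smoothed"))
        assert abs(z.grid.mean()) < 1e-12
        assert z.grid.std() == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        grid = rng.uniform(0, 5, size=(60, 40))
        z1 = zscore_map(DensityMap(grid=grid, stage="smoothed"))
        z2 = zscore_map(DensityMap(grid=3.5 * grid + 7.0, stage="smoothed"))
        np.testing.assert_allclose(z1.grid, z2.grid, atol=1e-10)

    def test_constant_map_rejected(self):
        with pytest.raises(DegenerateMapError):
            zscore_map(DensityMap(grid=np.ones((10, 10)), stage="smoothed"))

    def test_stage_order_enforced(self, rng):
        grid = rng.uniform(0, 1, size=(20, 20))
        z = zscore_map(DensityMap(grid=grid, stage="raw"))
        with pytest.raises(StageError):
            smooth_map(z)  # cannot smooth after z-scoring
        marg = marginal_maps({"a": z, "b": zscore_map(DensityMap(grid=grid**2, stage="raw"))})
        with pytest.raises(StageError):
            zscore_map(marg["a"])  # cannot z-score a marginal map
        with pytest.raises(StageError):
            marginal_maps({"a": DensityMap(grid=grid, stage="raw"), "b": z})


class TestMarginalMaps:
    def test_marginals_sum_to_zero_and_match_cellwise_oracle(self, rng):
        maps = {
            k: zscore_map(DensityMap(grid=rng.uniform(0, 1, size=(30, 20)), stage="smoothed"))
            for k in "abc"
        }
        marg = marginal_maps(maps)
        total = sum(m.grid for m in marg.values())
        np.testing.assert_allclose(total, 0.0, atol=1e-9)
        grand = (maps["a"].grid + maps["b"].grid + maps["c"].grid) / 3.0
        np.testing.assert_allclose(marg["b"].grid, maps["b"].grid - grand, atol=1e-12)

    def test_identical_maps_give_zero_marginals(self, rng):
        grid = rng.uniform(0, 1, size=(30, 20))
        z = zscore_map(DensityMap(grid=grid, stage="smoothed"))
        marg = marginal_maps({"a": z, "b": dataclasses.replace(z)})
        np.testing.assert_allclose(marg["a"].grid, 0.0, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        a = zscore_map(DensityMap(grid=rng.uniform(0, 1, (30, 20)), stage="smoothed"))
        b = zscore_map(DensityMap(grid=rng.uniform(0, 1, (20, 30)), stage="smoothed"))
        with pytest.raises(ValueError, match="shape"):
            marginal_maps({"a": a, "b": b})


class TestMapCorrelation:
    def test_self_and_negation(self, rng):
        grid = rng.uniform(0, 1, size=(30, 20))
        assert map_correlation(grid, grid) == pytest.approx(1.0)
        assert map_correlation(grid, -grid) == pytest.approx(-1.0)

    def test_matches_flattened_pearson(self, rng):
        a = rng.uniform(0, 1, size=(16, 12))
        b = np.roll(a, 3, axis=0) + rng.normal(0, 0.1, size=a.shape)
        expected = stats.pearsonr(a.ravel(), b.ravel()).statistic
        assert map_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateMapError):
            map_correlation(np.ones((5, 5)), np.eye(5))


class TestCategoryFdms:
    def test_disjoint_hotspots_peak_at_own_landmark(self, disjoint_dataset, geom):
        from gazemark.synthetic_scanpaths import DIAGNOSTIC_LANDMARKS, LandmarkSet

        fixations, trials, _ = disjoint_dataset
        maps = marginal_maps(category_fdms(fixations, trials, geom=geom))
        landmarks = LandmarkSet().points
        for emotion, m in maps.items():
            y, x = np.unravel_index(np.argmax(m.grid), m.grid.shape)
            lx, ly = landmarks[DIAGNOSTIC_LANDMARKS[emotion]]
            assert abs(x - lx) <= 1 and abs(y - ly) <= 1

    def test_correct_only_scoping_counts(self, small_dataset, geom):
        fixations, trials, _ = small_dataset
        maps = category_fdms(
            fixations, trials, spec=FdmSpec(trial_scope="correct_only"), geom=geom
        )
        for emotion, m in maps.items():
            expected = int((trials["correct"] & (trials["emotion"] == emotion)).sum())
            assert m.n_trials == expected

    def test_excluding_sole_participant_errors(self, geom):
        fix = make_fixations([("P01", "T001", 1, 512.0, 384.0, 100.0, 0.0)])
        trials = make_trials([_centered_trial()])
        with pytest.raises(ValueError):
            category_fdms(fix, trials, exclude_participant="P01", geom=geom)

    def test_marginal_maps_translation_covariant(self, geom):
        # shift every fixation by (dx, dy); interior cells of each marginal
        # map shift along (boundary effects excluded by a wide margin)
        cfg = default_config(seed=13, n_participants=2, identities=2)
        fix, trials, _ = generate_dataset(cfg)
        dx, dy = 9, -7
        shifted = fix.assign(x_screen=fix["x_screen"] + dx, y_screen=fix["y_screen"] + dy)
        m0 = marginal_maps(category_fdms(fix, trials, geom=geom))
        m1 = marginal_maps(category_fdms(shifted, trials, geom=geom))
        border = 80
        for emotion in m0:
            a = m0[emotion].grid[border:-border, border:-border]
            b = m1[emotion].grid[border + dy : -border + dy, border + dx : -border + dx]
            # z-scoring rescales slightly when mass crosses the border, so
            # compare up to an affine fit
            r = stats.pearsonr(a.ravel(), b.ravel()).statistic
            assert r > 0.999


class TestSimilarityContrast:
    def test_self_comparison_gives_perfect_within(self, small_dataset, geom):
        fixations, trials, _ = small_dataset
        spec = FdmSpec()
        res = similarity_contrast(fixations, trials, spec, spec, geom=geom)
        np.testing.assert_allclose(res.per_participant["within_r"], 1.0, atol=1e-9)
        assert (res.per_participant["between_r"] < 1.0).all()
        assert res.t > 0
        assert res.df == len(res.per_participant) - 1

    def test_category_structure_recovered(self, small_dataset, geom):
        fixations, trials, _ = small_dataset
        res = similarity_contrast(
            fixations,
            trials,
            FdmSpec(trial_scope="correct_only"),
            FdmSpec(trial_scope="incorrect_only"),
            geom=geom,
        )
        assert res.p < 0.05
        assert res.per_participant["within_r"].mean() > res.per_participant["between_r"].mean()


class TestCrossConditionSimilarity:
    def test_spotlight_divergence_yields_lowest_spotlight_pairs(self, geom):
        cfg = spotlight_divergent_config(seed=31, n_participants=4, identities=2)
        fix, trials, _ = generate_dataset(cfg)
        table = cross_condition_similarity(fix, trials, geom=geom)
        table = table.sort_values("mean_r")
        lowest = table.head(3)
        assert all(
            "spotlight" in (row.condition_a, row.condition_b)
            for row in lowest.itertuples()
        )

    def test_single_emotion_identical_maps(self, geom):
        # same fixation pattern in every condition -> all pair means 1
        rows, trial_rows = [], []
        for c_idx, cond in enumerate(("unrestricted", "blindspot", "neutral_blindspot", "spotlight")):
            tid = f"T{c_idx + 1:03d}"
            trial_rows.append(("P01", tid, "anger", cond, 1, 512.0, 384.0, "anger", 4.0))
            for i, (x, y) in enumerate([(500, 360), (520, 400), (480, 380)]):
                rows.append(("P01", tid, i + 1, float(x), float(y), 150.0, 0.0))
        res = cross_condition_similarity(
            make_fixations(rows), make_trials(trial_rows), geom=geom
        )
        np.testing.assert_allclose(res["mean_r"], 1.0, atol=1e-9)


class TestRefixationMap:
    def test_separated_fixations_give_zero_map(self, geom):
        fix = make_fixations(
            [
                ("P01", "T001", 1, 400.0, 300.0, 100.0, 0.0),
                ("P01", "T001", 2, 600.0, 500.0, 100.0, 0.0),
            ]
        )
        trials = make_trials([_centered_trial()])
        m = refixation_map(fix, trials, geom=geom)
        assert m.grid.sum() == 0.0

    def test_coincident_pair_counts_later_fixation_once(self, geom):
        fix = make_fixations(
            [
                ("P01", "T001", 1, 500.0, 400.0, 100.0, 0.0),
                ("P01", "T001", 2, 500.0, 400.0, 100.0, 0.0),
            ]
        )
        trials = make_trials([_centered_trial()])
        m = refixation_map(fix, trials, geom=geom)
        assert m.grid.sum() == 1.0
        assert m.grid[304, 180] == 1.0  # image frame (180, 304)

    def test_total_matches_pairwise_oracle(self, geom, rng):
        rows, trial_rows = [], []
        expected = 0
        for t in range(12):
            tid = f"T{t + 1:03d}"
            trial_rows.append(("P01", tid, "anger", "unrestricted", 1, 512.0, 384.0, "anger", 4.0))
            n = rng.integers(2, 9)
            pts = rng.uniform([330, 100], [700, 660], size=(n, 2))
            for i, (x, y) in enumerate(pts):
                rows.append(("P01", tid, i + 1, x, y, 100.0, 0.0))
            for j in range(1, n):
                if any(np.hypot(*(pts[j] - pts[i])) <= 62.0 for i in range(j)):
                    xi, yi = pts[j, 0] - 320, pts[j, 1] - 96
                    if 0 <= xi < 384 and 0 <= yi < 576:
                        expected += 1
        m = refixation_map(make_fixations(rows), make_trials(trial_rows), geom=geom)
        assert m.grid.sum() == expected
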