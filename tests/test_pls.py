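"""NIPALS PLS1, cross-validation, model search, validation and RPD scoring."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from nirscalib import (
    ConfigError,
    DataError,
    GeneratorConfig,
    ModelingError,
    PretreatmentSpec,
    ReferenceTable,
    WindowSet,
    calibrate,
    cross_validate,
    external_validate,
    fit_pls,
    global_recalibrate,
    grid_search,
    leaderboard_frame,
    load_model,
    metrics,
    predict,
    rpd,
    save_model,
    select_rank,
    simulate_dataset,
    split_calibration_validation,
)
from nirscalib.pls import SplitSpec, _nipals, default_window_candidates


class TestNipalsFit:
    def test_single_proportional_variable_rank1_exact(self, rng):
        X = rng.normal(size=(20, 6))
        y = 3.0 * X[:, 2]
        m = fit_pls(X[:, [2]], y, rank=1)
        fitted = m.y_mean + (X[:, [2]] - m.x_mean) @ m.coefficients
        np.testing.assert_allclose(fitted, y, atol=1e-10)

    def test_small_exact_system_matches_normal_equations(self):
        # y = x1 + 2*x2 solves the system exactly; rank-2 PLS must reproduce it
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([1.0, 2.0, 3.0])
        m = fit_pls(X, y, rank=2)
        fitted = m.y_mean + (X - m.x_mean) @ m.coefficients
        np.testing.assert_allclose(fitted, y, atol=1e-10)
        np.testing.assert_allclose(m.coefficients, [1.0, 2.0], atol=1e-8)

    def test_full_rank_equals_ols(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 50))
            p = int(rng.integers(2, min(20, n - 1) + 1))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            m = fit_pls(X, y, rank=p)
            beta = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)[0]
            np.testing.assert_allclose(m.coefficients, beta, atol=1e-6)

    def test_matches_sklearn_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(40, 25))
        y = rng.normal(size=40) + 2.0 * X[:, 0]
        m = fit_pls(X, y, rank=5)
        sk = sklearn.PLSRegression(n_components=5, scale=False).fit(X, y)
        ours = m.y_mean + (X - m.x_mean) @ m.coefficients
        np.testing.assert_allclose(ours, sk.predict(X).ravel(), atol=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        _, _, _, T = _nipals(X - X.mean(0), y - y.mean(), 6)
        G = T.T @ T
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8 * np.diag(G).max()

    def test_rmsec_monotone_in_rank(self, rng):
        X = rng.normal(size=(40, 15))
        y = rng.normal(size=40)
        rmsecs = []
        for r in range(1, 10):
            m = fit_pls(X, y, rank=r)
            fitted = m.y_mean + (X - m.x_mean) @ m.coefficients
            rmsecs.append(np.sqrt(np.mean((fitted - y) ** 2)))
        assert all(a >= b - 1e-10 for a, b in zip(rmsecs, rmsecs[1:]))

    def test_rank_exceeding_data_rank_names_component(self, rng):
        X = np.tile(rng.normal(size=(1, 5)), (10, 1)) + 0.0  # rank-0 after centering
        X[:, 0] += rng.normal(size=10)  # data rank 1
        y = X[:, 0].copy()
        with pytest.raises(ModelingError, match="component 2"):
            fit_pls(X, y, rank=3)


class TestMetrics:
    def test_table_style_rpd_worked_examples(self):
        assert round(rpd(7.62, 0.74), 2) == 10.30
        assert round(rpd(6.08, 2.51), 2) == 2.42

    def test_constant_predictor_r2_zero(self, rng):
        y = rng.normal(size=30)
        stats = metrics(y, np.full(30, y.mean()), sd_ref=1.0)
        assert stats["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_prediction_infinite_rpd(self, rng):
        y = rng.normal(loc=5, size=10)
        stats = metrics(y, y.copy(), sd_ref=2.0)
        assert stats["rmse"] == 0.0 and np.isinf(stats["rpd"])

    def test_bias_sign(self):
        stats = metrics(np.array([1.0, 2.0]), np.array([2.0, 3.0]), sd_ref=1.0)
        assert stats["bias"] == pytest.approx(1.0)

    def test_input_validation(self):
        with pytest.raises(DataError):
            metrics([1.0], [1.0], sd_ref=1.0)
        with pytest.raises(DataError):
            metrics([1.0, 2.0], [1.0, 2.0], sd_ref=0.0)


class TestSplit:
    def test_extremes_forced_into_calibration(self):
        ref = ReferenceTable([f"g{i}" for i in range(10)], "RPR", "N·mm⁻²",
                             np.arange(1.0, 11.0))
        split = split_calibration_validation(ref, ratio=0.8, seed=0)
        assert len(split.calibration_ids) == 8 and len(split.validation_ids) == 2
        assert "g0" in split.calibration_ids and "g9" in split.calibration_ids

    def test_rounding_at_four_to_one(self, rng):
        ref = ReferenceTable([f"g{i}" for i in range(526)], "RPR", "N·mm⁻²",
                             rng.uniform(20, 80, 526))
        split = split_calibration_validation(ref, ratio=0.8, seed=1)
        assert (len(split.calibration_ids), len(split.validation_ids)) == (421, 105)

    def test_same_seed_identical(self, rng):
        ref = ReferenceTable([f"g{i}" for i in range(50)], "RPR", "N·mm⁻²",
                             rng.uniform(20, 80, 50))
        a = split_calibration_validation(ref, 0.8, seed=7)
        b = split_calibration_validation(ref, 0.8, seed=7)
        assert a.calibration_ids == b.calibration_ids
        assert a.validation_ids == b.validation_ids

    def test_bad_ratio_rejected(self, rng):
        ref = ReferenceTable([f"g{i}" for i in range(20)], "RPR", "N·mm⁻²",
                             rng.uniform(20, 80, 20))
        with pytest.raises(ConfigError, match="ratio"):
            split_calibration_validation(ref, ratio=1.2, seed=0)

    def test_overlapping_split_rejected(self):
        with pytest.raises(DataError, match="overlap"):
            SplitSpec(["a", "b"], ["b", "c"], 0.8, 0)


class TestCrossValidation:
    def test_loo_equals_bruteforce_refitting(self, rng):
        n, p, rank = 30, 8, 4
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n) * 0.3
        cv = cross_validate(X, y, rank, n_segments=n, seed=2)
        brute = np.empty(n)
        for i in range(n):
            keep = np.r_[0:i, i + 1 : n]
            m = fit_pls(X[keep], y[keep], rank)
            brute[i] = m.y_mean + (X[i] - m.x_mean) @ m.coefficients
        np.testing.assert_array_equal(cv["predictions"], brute)

    def test_noiseless_linear_y_near_zero_rmsecv(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0, 1.0]) + 5.0
        cv = cross_validate(X, y, rank=6, n_segments=5, seed=3)
        assert cv["rmsecv"] < 1e-8

    def test_same_seed_same_segments(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        a = cross_validate(X, y, 2, 5, seed=11)
        b = cross_validate(X, y, 2, 5, seed=11)
        for seg_a, seg_b in zip(a["segments"], b["segments"]):
            np.testing.assert_array_equal(seg_a, seg_b)

    def test_tiny_segments_rejected_unless_loo(self, rng):
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        with pytest.raises(ModelingError, match="size < 2"):
            cross_validate(X, y, 2, n_segments=5, seed=0)
        cross_validate(X, y, 2, n_segments=9, seed=0)  # LOO allowed


class TestSelectRank:
    def test_three_latent_factors_low_noise(self, rng):
        n, p = 80, 40
        T = rng.normal(size=(n, 3))
        P = rng.normal(size=(3, p))
        X = T @ P + rng.normal(size=(n, p)) * 0.01
        y = T @ np.array([1.0, -1.0, 2.0]) + rng.normal(size=n) * 0.05
        r = select_rank(X, y, max_rank=10, n_segments=5, seed=4)
        assert r <= 5
        cv = cross_validate(X, y, r, 5, seed=4)
        assert cv["rmsecv"] < 0.15

    def test_pure_noise_no_overfit_escape(self, rng):
        X = rng.normal(size=(60, 30))
        y = rng.normal(size=60)
        r = select_rank(X, y, max_rank=15, n_segments=5, seed=5)
        cv = cross_validate(X, y, r, 5, seed=5)
        assert r <= 3
        assert cv["r2cv"] <= 0.2

    def test_max_rank_one_returns_one(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        assert select_rank(X, y, max_rank=1, n_segments=4, seed=0) == 1

    def test_parsimony_never_larger_than_argmin(self, rng):
        X = rng.normal(size=(50, 20))
        y = X[:, 0] + rng.normal(size=50) * 0.5
        r_pars = select_rank(X, y, 10, 5, seed=6, parsimony=True)
        r_argmin = select_rank(X, y, 10, 5, seed=6, parsimony=False)
        assert r_pars <= r_argmin


class TestPredictAndPersistence:
    def test_calibration_predictions_reproduced(self, small_dataset):
        _, data = small_dataset
        s, ref = data["spectra"], data["reference"]
        m = calibrate(s, ref, PretreatmentSpec("SNV"), None, rank=6, seed=0)
        y_hat = predict(m, s)
        fitted = metrics(ref.values, y_hat, sd_ref=m.y_sd)
        assert fitted["r2"] > 0.9

    def test_windowed_model_round_trips_through_json(self, small_dataset, tmp_path):
        cfg, data = small_dataset
        s, ref = data["spectra"], data["reference"]
        w = WindowSet([(4500.0, 7000.0), (9000.0, 11500.0)])
        m = calibrate(s, ref, PretreatmentSpec("MSC"), w, rank=5, seed=0)
        save_model(m, tmp_path / "model.json")
        back = load_model(tmp_path / "model.json")
        np.testing.assert_allclose(predict(back, s), predict(m, s), atol=1e-12)
        assert back.windows.intervals == m.windows.intervals

    def test_grid_mismatch_names_selected_range(self, small_dataset):
        _, data = small_dataset
        s, ref = data["spectra"], data["reference"]
        w = WindowSet([(9000.0, 11500.0)])
        m = calibrate(s, ref, PretreatmentSpec("NONE"), w, rank=3, seed=0)
        from nirscalib import SpectraSet, apply_windows

        truncated = apply_windows(s, WindowSet([(4000.0, 8000.0)]))
        with pytest.raises(DataError, match="9000"):
            predict(m, truncated)

    def test_prediction_mean_equals_y_mean_on_calibration_set(self, small_dataset):
        _, data = small_dataset
        s, ref = data["spectra"], data["reference"]
        m = calibrate(s, ref, PretreatmentSpec("NONE"), None, rank=4, seed=0)
        assert predict(m, s).mean() == pytest.approx(m.y_mean, abs=1e-8)


class TestExternalValidation:
    def test_leakage_guard(self, small_dataset):
        _, data = small_dataset
        s, ref = data["spectra"], data["reference"]
        m = calibrate(s, ref, PretreatmentSpec("NONE"), None, rank=4, seed=0)
        with pytest.raises(DataError, match="leakage"):
            external_validate(m, s, ref)

    def test_generalization_gap_small_across_seeds(self):
        gaps = []
        for seed in range(1, 6):
            cfg = GeneratorConfig(n_samples=150, n_points=300, seed=seed)
            data = simulate_dataset(cfg)
            s, ref = data["spectra"], data["reference"]
            split = split_calibration_validation(ref, 0.8, seed=seed)
            scal, rcal = s.subset(split.calibration_ids), ref.subset(split.calibration_ids)
            sval, rval = s.subset(split.validation_ids), ref.subset(split.validation_ids)
            pre = PretreatmentSpec("SNV")
            r = select_rank(scal.values, rcal.values, 12, 5, seed, pretreatment=pre, grid=scal.grid)
            cv = cross_validate(scal.values, rcal.values, r, 5, seed, pretreatment=pre, grid=scal.grid)
            m = calibrate(scal, rcal, pre, None, r, seed=seed)
            ext = external_validate(m, sval, rval)
            gaps.append(abs(ext["r2ev"] - cv["r2cv"]))
        assert max(gaps) < 0.05


class TestGridSearch:
    def test_single_candidate_single_row(self, small_dataset):
        _, data = small_dataset
        s, ref = data["spectra"], data["reference"]
        reports = grid_search(s, ref, [PretreatmentSpec("NONE")], [None], 8, 5, seed=0)
        assert len(reports) == 1
        assert reports[0].pretreatment == "NONE"

    def test_leaderboard_sorted_by_rmsecv(self, small_dataset):
        _, data = small_dataset
        s, ref = data["spectra"], data["reference"]
        pres = [PretreatmentSpec(m) for m in ("NONE", "SNV", "COE", "FD")]
        reports = grid_search(s, ref, pres, [None], 8, 5, seed=0)
        rmsecvs = [r.rmsecv for r in reports]
        assert rmsecvs == sorted(rmsecvs)
        frame = leaderboard_frame(reports)
        assert list(frame["RMSECV"]) == sorted(frame["RMSECV"])

    def test_all_candidates_failing_aggregated(self, small_dataset):
        _, data = small_dataset
        s, ref = data["spectra"], data["reference"]
        dead = WindowSet([(1.0, 2.0)])  # outside the grid
        with pytest.raises(ModelingError, match="all grid-search candidates failed"):
            grid_search(s, ref, [PretreatmentSpec("NONE")], [dead], 5, 5, seed=0)

    def test_default_window_candidates_cover_two_interval_unions(self):
        grid = np.linspace(4000.0, 12000.0, 200)
        cands = default_window_candidates(grid, n_blocks=4, max_runs=2)
        single = [c for c in cands if len(c.intervals) == 1]
        double = [c for c in cands if len(c.intervals) == 2]
        assert len(single) == 10  # 4+3+2+1 contiguous runs
        assert len(double) == 15  # disjoint non-adjacent run pairs
        for c in cands:
            assert (grid >= c.intervals[0][0] - 1).any()


class TestGlobalRecalibration:
    def test_empty_validation_reproduces_calibration_report(self, small_dataset):
        _, data = small_dataset
        s, ref = data["spectra"], data["reference"]
        pre = PretreatmentSpec("SNV")
        base = grid_search(s, ref, [pre], [None], 8, 5, seed=3)[0]
        split = SplitSpec(list(ref.sample_ids), [], 1.0, 3)
        glob = global_recalibrate(split, s, ref, pre, None, 8, 5, seed=3)
        assert glob.rank == base.rank
        assert glob.rmsecv == pytest.approx(base.rmsecv, rel=1e-12)
        assert glob.stage == "global"

    def test_union_sample_count(self, small_dataset):
        _, data = small_dataset
        s, ref = data["spectra"], data["reference"]
        split = split_calibration_validation(ref, 0.8, seed=1)
        glob = global_recalibrate(split, s, ref, PretreatmentSpec("SNV"), None, 8, 5, seed=1)
        assert glob.n == len(split.calibration_ids) + len(split.validation_ids)

    def test_no_degradation_versus_split_calibration(self):
        ratios = []
        for seed in range(1, 6):
            cfg = GeneratorConfig(n_samples=150, n_points=300, seed=seed)
            data = simulate_dataset(cfg)
            s, ref = data["spectra"], data["reference"]
            split = split_calibration_validation(ref, 0.8, seed=seed)
            scal, rcal = s.subset(split.calibration_ids), ref.subset(split.calibration_ids)
            pre = PretreatmentSpec("SNV")
            base = grid_search(scal, rcal, [pre], [None], 10, 5, seed=seed)[0]
            glob = global_recalibrate(split, s, ref, pre, None, 10, 5, seed=seed)
            ratios.append(glob.rmsecv / base.rmsecv)
        assert max(ratios) < 1.10


def test_rpd_degrades_monotonically_with_reference_noise():
    noise_levels = np.linspace(0.5, 8.0, 10)
    rpds = []
    for i, noise in enumerate(noise_levels):
        cfg = GeneratorConfig(
            n_samples=150, n_points=300, seed=100 + i, reference_error_sd=float(noise)
        )
        data = simulate_dataset(cfg)
        s, ref = data["spectra"], data["reference"]
        cv = cross_validate(
            s.values, ref.values, 8, 5, seed=i,
            pretreatment=PretreatmentSpec("SNV"), grid=s.grid,
        )
        rpds.append(cv["rpd_cv"])
    rho, _ = spearmanr(noise_levels, rpds)
    assert rho < -0.9
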