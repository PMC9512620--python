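"""Coarse-to-fine pRF estimation: recovery, gating, HRF fitting."""

import numpy as np
import pandas as pd
import pytest

import prfscotoma as pf
from prfscotoma.fitting import FitConfig, _CoarseEngine, variance_explained
from prfscotoma.prf_model import (
    CANONICAL_HRF,
    ModelVariant,
    PRFParams,
    predict_timecourse,
)
from prfscotoma.stimulus import build_sequence, study_config
from prfscotoma.synthetic import GroundTruthVoxel


class TestVarianceExplained:
    @pytest.mark.parametrize(
        "obs,pred,expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
            ([1, 2, 3, 4], [2.5, 2.5, 2.5, 2.5], 0.0),
            ([1, 2, 3, 4], [1, 2, 3, 5], 0.8),  # 1 - 1/5 by hand
        ],
    )
    def test_hand_computed_values(self, obs, pred, expected):
        assert variance_explained(obs, pred) == pytest.approx(expected)

    def test_constant_observed_is_flagged(self):
        assert np.isnan(variance_explained([2, 2, 2], [1, 2, 3]))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            variance_explained([1, 2], [1, 2, 3])


@pytest.fixture(scope="module")
def tiny_setup():
    """Reduced search space where a brute-force oracle is affordable."""
    seq = build_sequence(study_config(scotoma_radius_deg=0.0, grid_resolution=41))
    cfg = FitConfig(
        variant=ModelVariant.GAUSSIAN_CANONICAL_HRF,
        grid_spacing_deg=1.0,
        sigma_levels=(0.5, 1.0, 2.0),
    )
    return seq, cfg


class TestCoarseFit:
    def test_on_grid_truth_recovered_exactly(self, tiny_setup):
        seq, cfg = tiny_setup
        truth = PRFParams(2.0, -1.0, sigma=1.0, beta=1.3, baseline=0.2)
        ts = predict_timecourse(truth, seq)
        params, ve = pf.coarse_fit(ts, seq, cfg)
        assert (params.x, params.y, params.sigma) == (2.0, -1.0, 1.0)
        assert ve == pytest.approx(1.0, abs=1e-9)
        assert params.beta == pytest.approx(1.3, rel=1e-6)
        assert params.baseline == pytest.approx(0.2, abs=1e-6)

    def test_matches_brute_force_search(self, tiny_setup):
        """Independent oracle: loop over every grid candidate with the
        public forward model and pick the best variance explained."""
        seq, cfg = tiny_setup
        rng = np.random.default_rng(3)
        engine = _CoarseEngine(seq, cfg)
        cand = list(zip(engine.xs, engine.ys, engine.sigmas))
        for _ in range(3):
            truth = PRFParams(
                rng.uniform(-4, 4), rng.uniform(-4, 4), rng.uniform(0.4, 2.2)
            )
            ts = predict_timecourse(truth, seq) + rng.normal(0, 0.3, seq.n_frames)
            best_ve, best_params = -np.inf, None
            for x, y, s in cand:
                pred = predict_timecourse(PRFParams(x, y, s), seq)
                r = np.corrcoef(pred, ts)[0, 1]
                ve = max(r, 0.0) ** 2
                if ve > best_ve + 1e-12:
                    best_ve, best_params = ve, (x, y, s)
            params, ve = pf.coarse_fit(ts, seq, cfg)
            assert (params.x, params.y, params.sigma) == best_params
            assert ve == pytest.approx(best_ve, abs=1e-9)

    def test_off_grid_truth_lands_on_nearest_node(self, tiny_setup):
        seq, cfg = tiny_setup
        truth = PRFParams(2.2, -0.9, sigma=1.1)
        ts = predict_timecourse(truth, seq)
        params, _ = pf.coarse_fit(ts, seq, cfg)
        assert params.x == 2.0 and params.y == -1.0 and params.sigma == 1.0


class TestRefineFit:
    def test_off_grid_recovery(self, tiny_setup):
        seq, cfg = tiny_setup
        rng = np.random.default_rng(12)
        for _ in range(5):
            truth = PRFParams(
                rng.uniform(-4, 4), rng.uniform(-4, 4), rng.uniform(0.5, 2.0)
            )
            ts = predict_timecourse(truth, seq)
            start, ve0 = pf.coarse_fit(ts, seq, cfg)
            params, ve = pf.refine_fit(start, ts, seq, cfg)
            assert abs(params.x - truth.x) < 0.05
            assert abs(params.y - truth.y) < 0.05
            assert abs(params.sigma - truth.sigma) / truth.sigma < 0.05
            assert ve >= ve0 - 1e-12  # refinement never regresses

    def test_start_at_truth_stays(self, tiny_setup):
        seq, cfg = tiny_setup
        truth = PRFParams(1.5, 0.5, sigma=0.9)
        ts = predict_timecourse(truth, seq)
        params, ve = pf.refine_fit(truth, ts, seq, cfg)
        assert ve == pytest.approx(1.0, abs=1e-9)
        assert abs(params.x - 1.5) < 1e-3 and abs(params.sigma - 0.9) / 0.9 < 1e-2


class TestRunHRFFit:
    def _make_run(self, seq, delay, n_vox=80, seed=0):
        pop = pf.sample_population(n_vox, seed=seed)
        pop = pf.calibrate_amplitudes(pop, seq)
        h = CANONICAL_HRF.with_peak(delay, CANONICAL_HRF.peak_dispersion_s)
        return pf.simulate_run(pop, seq, h, noise_sd=0.0).timeseries

    def test_recovers_shifted_peak_delay(self, small_full_seq):
        """Recovery oracle: noiseless data generated with a 6.8 s peak."""
        Y = self._make_run(small_full_seq, delay=6.8)
        table = pf.fit_run(Y, small_full_seq, FitConfig())
        assert table.hrf_peak_delay_s.iloc[0] == pytest.approx(6.8, abs=0.4)

    def test_canonical_variant_keeps_canonical_kernel(self, small_full_seq):
        Y = self._make_run(small_full_seq, delay=6.8, n_vox=60)
        cfg = FitConfig(variant=ModelVariant.GAUSSIAN_CANONICAL_HRF)
        table = pf.fit_run(Y, small_full_seq, cfg)
        assert (table.hrf_peak_delay_s == CANONICAL_HRF.peak_delay_s).all()

    def test_too_few_gated_voxels_falls_back(self, small_full_seq):
        rng = np.random.default_rng(1)
        Y = rng.normal(0, 1, (30, small_full_seq.n_frames))
        table = pf.fit_run(Y, small_full_seq, FitConfig())
        assert (table.hrf_peak_delay_s == CANONICAL_HRF.peak_delay_s).all()

    def test_runs_get_independent_hrfs(self, small_full_seq):
        ya = self._make_run(small_full_seq, delay=5.6, seed=1)
        yb = self._make_run(small_full_seq, delay=6.6, seed=2)
        ta = pf.fit_run(ya, small_full_seq, FitConfig())
        tb = pf.fit_run(yb, small_full_seq, FitConfig())
        assert ta.hrf_peak_delay_s.iloc[0] != tb.hrf_peak_delay_s.iloc[0]


class TestFitRun:
    def test_noise_voxels_fall_below_the_gate(self, tiny_setup):
        """Simulation oracle: pure-noise voxels rarely clear the 10%
        variance-explained inclusion gate."""
        seq, cfg = tiny_setup
        rng = np.random.default_rng(21)
        Y = rng.normal(0, 1, (300, seq.n_frames))
        table = pf.fit_run(Y, seq, cfg)
        excluded = (table.variance_explained <= 0.10).mean()
        assert excluded > 0.95

    def test_deterministic_output(self, tiny_setup):
        seq, cfg = tiny_setup
        rng = np.random.default_rng(5)
        Y = rng.normal(0, 1, (20, seq.n_frames)) + predict_timecourse(
            PRFParams(1.2, 0.4, 0.9), seq
        )
        a = pf.fit_run(Y, seq, cfg)
        b = pf.fit_run(Y, seq, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_gate_monotonicity(self, study_fits):
        table = study_fits[0]["s1r1"]
        low = set(table.loc[table.variance_explained > 0.05, "voxel_id"])
        high = set(table.loc[table.variance_explained > 0.20, "voxel_id"])
        assert high <= low

    def test_empty_input(self, small_full_seq):
        table = pf.fit_run(
            np.empty((0, small_full_seq.n_frames)), small_full_seq, FitConfig()
        )
        assert len(table) == 0


class TestFitPopulation:
    def test_six_analyses_per_subject(self, study_fits):
        assert set(study_fits[0]) == {
            "s1r1",
            "s1r2",
            "s2r1",
            "s2r2",
            "s1avg",
            "s2avg",
        }

    def test_scotoma_naive_bias(self, small_full_seq, small_scotoma_seq):
        """Noiseless scotoma acquisition fitted full-field: no gated
        small pRF keeps a center inside the 2° scotoma, and centers
        pile up in the border band (1.8°–2.6°) relative to a full-field
        acquisition of the same population."""
        pop = pf.sample_population(300, seed=31)
        pop = pf.calibrate_amplitudes(pop, small_full_seq)
        cfg = FitConfig(variant=ModelVariant.GAUSSIAN_CANONICAL_HRF)
        y_scot = pf.simulate_run(pop, small_scotoma_seq, noise_sd=0.0).timeseries
        y_full = pf.simulate_run(pop, small_full_seq, noise_sd=0.0).timeseries
        t_scot = pf.fit_run(y_scot, small_full_seq, cfg)
        t_full = pf.fit_run(y_full, small_full_seq, cfg)
        gated = t_scot[t_scot.variance_explained > 0.10]
        assert not (
            (gated.eccentricity < 2.0) & (gated.sigma < 0.5)
        ).any()
        g_full = t_full[t_full.variance_explained > 0.10]
        band = (1.8, 2.6)
        frac_scot = gated.eccentricity.between(*band).mean()
        frac_full = g_full.eccentricity.between(*band).mean()
        assert frac_scot > frac_full
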