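import itertools

import numpy as np
import pytest
from scipy import stats

from somatomap.er_design import generate_fast_er_sequence, generate_slow_er_sequence
from somatomap.glm import (
    compute_contrasts,
    delay_ratio,
    estimate_voxel_hrfs,
    fdr_step_up,
    fingertip_amplitudes,
    fit_glm,
    participant_average_hrf,
)
from somatomap.hemodynamics import HRFModel, build_design, double_gamma_hrf
from somatomap.preprocess import RunTimeseries, concatenate_runs
from somatomap.synthetic_data import gaussian_tuning, simulate_run

from conftest import make_patch, run_to_psc


class TestFitGLM:
    def test_noiseless_recovery(self, hrf):
        patch = make_patch(center=[1.5, 3.0, 4.8], sigma=[0.7, 1.5, 3.0], noise_sd=0.0)
        seq = generate_fast_er_sequence(0)
        run = simulate_run(patch, seq, hrf, 0.0, 0)
        res = fingertip_amplitudes(run_to_psc(run), seq, hrf)
        truth = patch.flat(patch.amplitude)[:, None] * gaussian_tuning(
            patch.flat(patch.prf_center), patch.flat(patch.prf_sigma)
        )
        np.testing.assert_allclose(res.finger_betas(), truth, atol=1e-8)

    def test_null_t_statistics_follow_student_t(self, hrf):
        """Pure-noise betas scaled by their SE follow Student-t(dof)."""
        rng = np.random.default_rng(0)
        seq = generate_fast_er_sequence(1)
        X = build_design(seq, "canonical", hrf)
        ts = RunTimeseries(rng.standard_normal((10_000, 126)))
        res = fit_glm(ts, X)
        t = res.betas[:, 0] / res.beta_se[:, 0]
        _, p = stats.kstest(t, stats.t(df=res.dof).cdf)
        assert p > 0.01
        assert res.dof == 126 - 6  # 5 fingers + intercept

    def test_se_scales_with_noise(self, hrf):
        rng = np.random.default_rng(1)
        seq = generate_fast_er_sequence(2)
        X = build_design(seq, "canonical", hrf)
        se = []
        for sd in (1.0, 2.0):
            ts = RunTimeseries(sd * rng.standard_normal((2000, 126)))
            se.append(fit_glm(ts, X).beta_se[:, :5].mean())
        assert se[1] / se[0] == pytest.approx(2.0, rel=0.05)

    def test_rank_deficiency_reported_with_columns(self):
        X = np.column_stack([np.ones(20), np.ones(20), np.arange(20.0)])
        ts = RunTimeseries(np.random.default_rng(0).standard_normal((2, 20)))
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_glm(ts, X, labels=["a", "b", "c"])


class TestFIRDeconvolution:
    def test_isolated_events_recover_hrf_shape(self, hrf):
        """Slow ER with no overlap: FIR estimates reproduce the true
        response shape exactly on noiseless data."""
        patch = make_patch(center=3.0, sigma=0.05, noise_sd=0.0)
        seq = generate_slow_er_sequence(0)
        run = simulate_run(patch, seq, hrf, 0.0, 0)
        hrfs, _ = estimate_voxel_hrfs(run_to_psc(run), seq)
        np.testing.assert_allclose(hrfs[0, 2, :], hrf.samples, atol=1e-8)

    def test_overlapping_fast_er_resolved_by_deconvolution(self, hrf):
        """Heavy response overlap in fast ER is resolved exactly by the
        FIR GLM (linear superposition)."""
        patch = make_patch(center=[2.0, 4.0], sigma=[0.05, 1.0], noise_sd=0.0)
        seq = generate_fast_er_sequence(3)
        run = simulate_run(patch, seq, hrf, 0.0, 0)
        hrfs, _ = estimate_voxel_hrfs(run_to_psc(run), seq)
        w = gaussian_tuning(patch.flat(patch.prf_center), patch.flat(patch.prf_sigma))
        for v in range(2):
            for f in range(5):
                np.testing.assert_allclose(
                    hrfs[v, f, :], w[v, f] * hrf.samples, atol=1e-7
                )

    def test_fir_se_smaller_for_fast_than_slow(self, hrf):
        """At matched run count and noise, FIR estimate SEs are smaller
        for the fast than the slow ER design."""
        rng = np.random.default_rng(4)
        ses = {}
        for gen, name in [(generate_fast_er_sequence, "fast"),
                          (generate_slow_er_sequence, "slow")]:
            seq = gen(1)
            ts = RunTimeseries(rng.standard_normal((300, 126)))
            _, res = estimate_voxel_hrfs(ts, seq)
            ses[name] = res.beta_se[:, :100].mean()
        assert ses["fast"] < ses["slow"]


class TestParticipantHRF:
    def test_uniform_truth_recovered_normalized(self, hrf):
        n_vox, n_pts = 20, 20
        voxel_hrfs = np.tile(3.0 * hrf.samples, (n_vox, 5, 1))
        regions = {f: np.arange((f - 1) * 4, f * 4) for f in range(1, 6)}
        ph = participant_average_hrf(voxel_hrfs, regions)
        np.testing.assert_allclose(ph.samples, hrf.samples, atol=1e-12)
        assert ph.samples.sum() * 2.0 == pytest.approx(1.0)

    def test_region_permutation_invariance(self, hrf):
        rng = np.random.default_rng(0)
        voxel_hrfs = rng.standard_normal((30, 5, 20)) + hrf.samples
        regions = {f: rng.choice(30, 5, replace=False) for f in range(1, 6)}
        a = participant_average_hrf(voxel_hrfs, regions)
        shuffled = dict(reversed(list(regions.items())))
        b = participant_average_hrf(voxel_hrfs, shuffled)
        np.testing.assert_allclose(a.samples, b.samples)

    def test_empty_region_warned_all_empty_raises(self, hrf):
        voxel_hrfs = np.tile(hrf.samples, (10, 5, 1))
        with pytest.warns(UserWarning):
            participant_average_hrf(
                voxel_hrfs, {1: np.arange(3), 2: np.array([], dtype=int)}
            )
        with pytest.raises(ValueError):
            participant_average_hrf(voxel_hrfs, {1: np.array([], dtype=int)})

    def test_noisy_recovery_correlates_with_truth(self, hrf):
        """Two-step HRF estimation from noisy fast ER data stays highly
        correlated with the generating HRF at study noise levels."""
        centers = np.repeat([1, 2, 3, 4, 5], 8).astype(float)
        patch = make_patch(center=centers, sigma=0.8, noise_sd=1.0)
        seqs = [generate_fast_er_sequence(s) for s in range(4)]
        runs = [simulate_run(patch, s, hrf, 0.0, seed=i) for i, s in enumerate(seqs)]
        ts, cat = concatenate_runs([run_to_psc(r) for r in runs], seqs)
        hrfs, _ = estimate_voxel_hrfs(ts, cat)
        regions = {f: np.nonzero(np.round(centers) == f)[0] for f in range(1, 6)}
        ph = participant_average_hrf(hrfs, regions)
        r = np.corrcoef(ph.samples, hrf.samples)[0, 1]
        assert r > 0.95


class TestContrasts:
    def _result_for(self, betas_5, hrf, noise=0.0, seed=0):
        n_vox = betas_5.shape[0]
        seq = generate_fast_er_sequence(0)
        X = build_design(seq, "canonical", hrf)
        rng = np.random.default_rng(seed)
        clean = betas_5 @ X.values.T
        ts = RunTimeseries(clean + noise * rng.standard_normal((n_vox, 126)))
        return fit_glm(ts, X)

    def test_equal_betas_zero_preference_contrast(self, hrf):
        """Equal fingertip betas: the preference contrast estimate is zero
        and its t statistics are mean-zero noise."""
        res = self._result_for(np.ones((400, 5)), hrf, noise=0.1, seed=5)
        t, _ = compute_contrasts(res, "preference")
        contrast_values = res.finger_betas() - res.finger_betas().mean(
            axis=1, keepdims=True
        )
        assert abs(contrast_values.mean()) < 1e-3
        assert abs(t.mean()) < 4 / np.sqrt(t.size)

    def test_delta_tuned_voxel_prefers_its_finger(self, hrf):
        betas = np.zeros((1, 5))
        betas[0, 2] = 1.0
        res = self._result_for(betas, hrf, noise=0.05)
        _, p = compute_contrasts(res, "preference")
        assert p[0, 2] < 1e-6
        assert np.all(p[0, [0, 1, 3, 4]] > 0.05)

    def test_null_f_type_one_error(self, hrf):
        res = self._result_for(np.zeros((5000, 5)), hrf, noise=1.0, seed=2)
        for kind in ("main_effect_F", "any_positive_F"):
            _, p = compute_contrasts(res, kind)
            rate = (p < 0.05).mean()
            assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 5000)

    def test_unknown_kind(self, hrf):
        res = self._result_for(np.zeros((1, 5)), hrf, noise=1.0)
        with pytest.raises(ValueError):
            compute_contrasts(res, "bogus")


def bh_brute_force(p, q):
    """Literal BH step-up: reject all i <= max{i: p_(i) <= q*i/m}."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ps = p[order]
    kmax = 0
    for i in range(1, m + 1):
        if ps[i - 1] <= q * i / m:
            kmax = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:kmax]] = True
    return reject


class TestFDR:
    def test_single_p(self):
        rej, _ = fdr_step_up(np.array([0.04]), 0.05)
        assert rej.tolist() == [True]

    def test_hand_computed_example(self):
        rej, _ = fdr_step_up(np.array([0.01, 0.02, 0.04, 0.9]), 0.05)
        # thresholds q*i/m = .0125, .025, .0375, .05: p_(2)=0.02 <= .025
        # but p_(3)=0.04 > .0375 -> exactly the first two rejected
        assert rej.tolist() == [True, True, False, False]

    def test_matches_brute_force_exhaustively(self):
        grid = [0.001, 0.02, 0.04, 0.2, 0.9]
        for m in (1, 2, 3, 4, 5):
            for ps in itertools.product(grid, repeat=m):
                p = np.array(ps)
                np.testing.assert_array_equal(
                    fdr_step_up(p, 0.05)[0], bh_brute_force(p, 0.05),
                    err_msg=str(ps),
                )

    def test_adjusted_p_is_monotone_envelope(self):
        p = np.array([0.001, 0.01, 0.02, 0.9, 0.04])
        _, adj = fdr_step_up(p)
        m = p.size
        order = np.argsort(p)
        raw = m * p[order] / np.arange(1, m + 1)
        expected = np.minimum.accumulate(raw[::-1])[::-1]
        np.testing.assert_allclose(adj[order], np.minimum(expected, 1.0))

    def test_null_fdr_controlled(self):
        rng = np.random.default_rng(6)
        reps, m = 10_000, 16
        false_disc = 0
        for _ in range(reps):
            rej, _ = fdr_step_up(rng.uniform(size=m), 0.05)
            false_disc += rej.any()
        # all-null: FDR = FWER; within binomial error of q
        assert false_disc / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestDelayRatio:
    def _sim(self, hrf_gen, seed=0):
        patch = make_patch(center=[1, 2, 3, 4, 5], sigma=0.8, noise_sd=0.1)
        seq = generate_fast_er_sequence(0)
        run = simulate_run(patch, seq, hrf_gen, 0.0, seed)
        return run_to_psc(run), seq

    def test_canonical_data_ratio_exactly_zero_noiseless(self):
        can = double_gamma_hrf(dt=2.0)
        patch = make_patch(center=[1, 2, 3, 4, 5], sigma=0.8, noise_sd=0.0)
        seq = generate_fast_er_sequence(0)
        run = simulate_run(patch, seq, can, 0.0, 0)
        r = delay_ratio(run_to_psc(run), seq, can)
        np.testing.assert_allclose(r, 0.0, atol=1e-10)

    def test_earlier_response_positive_ratio_and_monotone(self):
        can = double_gamma_hrf(dt=2.0)
        means = []
        for shift in (-1.0, 0.0, 1.0):  # generating peak delay 6+shift
            gen = double_gamma_hrf(peak_delay=6.0 + shift,
                                   undershoot_delay=16.0 + shift, dt=2.0)
            ts, seq = self._sim(gen)
            means.append(np.nanmean(delay_ratio(ts, seq, can)))
        assert means[0] > 0  # earlier peak -> positive ratio
        assert means[0] > means[1] > means[2]  # monotone in delay


class TestSEOrderingFastVsSlow:
    def test_amplitude_se_smaller_for_fast(self, hrf):
        """Matched scan time and noise: the fast ER design yields smaller
        amplitude-estimate SEs than the slow ER design."""
        rng = np.random.default_rng(8)
        se = {}
        for gen, name in [(generate_fast_er_sequence, "fast"),
                          (generate_slow_er_sequence, "slow")]:
            seq = gen(0)
            ts = RunTimeseries(rng.standard_normal((200, 126)))
            res = fingertip_amplitudes(ts, seq, hrf)
            se[name] = res.beta_se[:, :5].mean()
        assert se["fast"] < se["slow"]
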