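"""Design assembly, OLS, contrasts, second level, FDR, conjunction."""

import numpy as np
import pytest
from scipy import stats

from gonogofmri.core import BOLDRun
from gonogofmri.glm import (
    StatMap,
    T_CAP,
    build_design,
    conjunction,
    contrast_tmap,
    fdr_threshold,
    fit_glm,
    second_level,
    smooth,
)
from gonogofmri.hrf import HRFParams, sample_at_tr
from gonogofmri.synthgen import GroundTruth, make_bold, make_roiset

from conftest import grid_trials, trial_table

TR = 2.5


class TestBuildDesign:
    def test_session_without_fa_flags_zero_column(self):
        trials = grid_trials(4, outcome="Hit")
        with pytest.warns(UserWarning):
            design = build_design(trials, HRFParams(), n_volumes=60, tr=TR)
        assert "FA" in design.zero_task_columns
        assert not design.column("FA").any()

    def test_single_event_column_is_tr_sampled_kernel(self):
        trials = grid_trials(1, start_vol=0)
        design = None
        with pytest.warns(UserWarning):
            design = build_design(trials, HRFParams(), n_volumes=20, tr=TR)
        expected = sample_at_tr(HRFParams(), TR, 30.0)
        np.testing.assert_allclose(design.column("Hit")[:12], expected,
                                   atol=1e-12)

    def test_overlapping_events_superpose(self):
        trials = grid_trials(2, start_vol=0, spacing_vol=3)
        with pytest.warns(UserWarning):
            design = build_design(trials, HRFParams(), n_volumes=30, tr=TR)
        h = sample_at_tr(HRFParams(), TR, 30.0)
        expected = np.zeros(30)
        for i in (0, 3):
            expected[i:i + 12] += h[:min(12, 30 - i)]
        np.testing.assert_allclose(design.column("Hit"), expected,
                                   atol=1e-12)

    def test_block_intercepts_and_rank_check(self):
        trials = grid_trials(4)
        with pytest.warns(UserWarning):
            design = build_design(trials, HRFParams(), n_volumes=60, tr=TR,
                                  block_bounds=[(0, 30), (30, 60)])
        assert "intercept_b0" in design.names
        assert "intercept_b1" in design.names
        assert design.column("intercept_b0").sum() == 30


class TestSmooth:
    def _impulse_run(self):
        data = np.zeros((21, 21, 15, 1))
        data[10, 10, 7, 0] = 1.0
        return BOLDRun(data=data, tr=TR)

    def test_zero_fwhm_is_identity(self):
        run = self._impulse_run()
        out = smooth(run, fwhm_um=0.0)
        np.testing.assert_array_equal(out.data, run.data)

    def test_impulse_response_has_requested_fwhm(self):
        run = self._impulse_run()
        out = smooth(run, fwhm_um=600.0)
        vol = out.data[..., 0]
        for axis, voxel_um in zip(range(3), run.voxel_size_um):
            profile = vol[tuple(
                slice(None) if a == axis else 10 if a < 2 else 7
                for a in range(3))]
            half = profile.max() / 2
            above = np.flatnonzero(profile >= half)
            # linear interpolation at the half-maximum crossings
            lo, hi = above[0], above[-1]

            def frac(i, j):
                return (profile[i] - half) / (profile[i] - profile[j])

            width = (hi - lo) + frac(hi, hi + 1) + frac(lo, lo - 1)
            fwhm_um = width * voxel_um
            assert fwhm_um == pytest.approx(600.0, rel=0.05)

    def test_constant_volume_unchanged(self):
        run = BOLDRun(data=np.full((8, 8, 6, 2), 7.0), tr=TR)
        out = smooth(run, fwhm_um=600.0)
        np.testing.assert_allclose(out.data, 7.0, atol=1e-10)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth(self._impulse_run(), fwhm_um=-1.0)


def _forward_run(betas, n_volumes=60, noise_sd=0.0, seed=0,
                 outcomes=("Hit", "FA")):
    """Single-voxel forward model with interleaved conditions."""
    onsets, kinds = [], []
    for i in range(8):
        onsets.append((4 + 6 * i) * TR)
        kinds.append(outcomes[i % len(outcomes)])
    trials = trial_table([o - 0.1 for o in onsets], kinds)
    trials["stimulus_onset"] = onsets
    h = sample_at_tr(HRFParams(), TR, 30.0)
    sig = np.full(n_volumes, 100.0)
    for onset, kind in zip(onsets, kinds):
        i = int(onset / TR)
        seg = h[:min(12, n_volumes - i)]
        sig[i:i + len(seg)] += betas.get(kind, 0.0) * seg
    rng = np.random.default_rng(seed)
    if noise_sd:
        sig = sig + rng.normal(0, noise_sd, n_volumes)
    bold = BOLDRun(data=sig[None, None, None, :], tr=TR)
    return bold, trials


class TestFitGlmAndContrast:
    def test_noiseless_betas_exact(self):
        bold, trials = _forward_run({"Hit": 1.0, "FA": 0.4})
        with pytest.warns(UserWarning):
            design = build_design(trials, HRFParams(), n_volumes=60, tr=TR)
        fit = fit_glm(bold, design)
        assert fit.beta_volume("Hit")[0, 0, 0] == pytest.approx(1.0, abs=1e-8)
        assert fit.beta_volume("FA")[0, 0, 0] == pytest.approx(0.4, abs=1e-8)
        assert fit.df == 60 - 3  # Hit, FA, intercept (CR/Nuisance4 dropped)

    def test_noiseless_t_sign_matches_beta_sign(self):
        bold, trials = _forward_run({"Hit": 1.0, "FA": -0.4})
        with pytest.warns(UserWarning):
            design = build_design(trials, HRFParams(), n_volumes=60, tr=TR)
        fit = fit_glm(bold, design)
        t_hit = contrast_tmap(fit, {"Hit": 1.0}).data[0, 0, 0]
        t_fa = contrast_tmap(fit, {"FA": 1.0}).data[0, 0, 0]
        assert t_hit == T_CAP and t_fa == -T_CAP

    def test_beta_recovery_unbiased_under_noise(self):
        # OLS unbiasedness, Monte-Carlo oracle: mean recovered beta within
        # 3 SE of truth over 100 seeds at SNR beta=1%, sigma=0.5%
        recovered = []
        for seed in range(100):
            bold, trials = _forward_run({"Hit": 1.0, "FA": 0.4},
                                        n_volumes=200, noise_sd=0.5,
                                        seed=seed)
            with pytest.warns(UserWarning):
                design = build_design(trials, HRFParams(), n_volumes=200,
                                      tr=TR)
            fit = fit_glm(bold, design)
            recovered.append(fit.beta_volume("Hit")[0, 0, 0])
        recovered = np.array(recovered)
        se = recovered.std(ddof=1) / np.sqrt(len(recovered))
        assert abs(recovered.mean() - 1.0) < 3 * se

    def test_null_t_calibrated(self):
        # permuted-onset (pure noise) design: empirical two-sided rejection
        # rate at alpha=0.05 within binomial CI over 400 voxels x seeds
        n_rej = 0
        n_tests = 400
        rng = np.random.default_rng(77)
        trials = grid_trials(8)
        with pytest.warns(UserWarning):
            design = build_design(trials, HRFParams(), n_volumes=100, tr=TR)
        crit = stats.t.ppf(0.975, 100 - 2)
        for _ in range(n_tests):
            sig = 100.0 + rng.normal(0, 1.0, 100)
            bold = BOLDRun(data=sig[None, None, None, :], tr=TR)
            fit = fit_glm(bold, design)
            t = contrast_tmap(fit, {"Hit": 1.0}).data[0, 0, 0]
            n_rej += abs(t) > crit
        # binomial CI: 0.05 * 400 = 20 +- 3 * sqrt(400*.05*.95) ~ 13
        assert abs(n_rej - 0.05 * n_tests) < 3 * np.sqrt(
            n_tests * 0.05 * 0.95)

    def test_zero_contrast_rejected(self):
        bold, trials = _forward_run({"Hit": 1.0})
        with pytest.warns(UserWarning):
            design = build_design(trials, HRFParams(), n_volumes=60, tr=TR)
        fit = fit_glm(bold, design)
        with pytest.raises(ValueError):
            contrast_tmap(fit, {"Hit": 0.0})
        with pytest.raises(ValueError):
            contrast_tmap(fit, {"CR": 1.0})  # empty condition

    def test_hippocampal_sign_pattern_recovered(self, small_rois):
        """Forward model with negative Hit and positive FA responses in the
        hippocampus yields the matching contrast signs after the full GLM."""
        truth = GroundTruth(noise_sd=0.1, drift_amp=0.0,
                            motion_spike_rate=0.0, roi_hrf_shift={}, seed=4)
        onsets, kinds = [], []
        for i in range(12):
            onsets.append((4 + 5 * i) * TR)
            kinds.append(["Hit", "FA", "CR"][i % 3])
        trials = trial_table([o - 0.1 for o in onsets], kinds)
        trials["stimulus_onset"] = onsets
        bold, _ = make_bold(trials, small_rois, truth, tr=TR, n_volumes=80)
        design = build_design(trials, HRFParams(), n_volumes=80, tr=TR)
        fit = fit_glm(bold, design, mask=small_rois.brain_mask())
        hit_fa = contrast_tmap(fit, {"Hit": 1.0, "FA": -1.0})
        hc = small_rois["HC"]
        assert (hit_fa.data[hc] < 0).all()   # beta_Hit=-0.3 < beta_FA=+0.7
        vs = small_rois["VS"]
        assert (hit_fa.data[vs] > 0).all()

    def test_concatenated_blocks_match_per_block_average(self):
        # concatenation equivalence on identical block designs
        bold1, trials1 = _forward_run({"Hit": 0.8, "FA": 0.2}, noise_sd=0.3,
                                      seed=1)
        bold2, _ = _forward_run({"Hit": 0.8, "FA": 0.2}, noise_sd=0.3,
                                seed=2)
        with pytest.warns(UserWarning):
            d1 = build_design(trials1, HRFParams(), n_volumes=60, tr=TR)
        b1 = fit_glm(bold1, d1).beta_volume("Hit")[0, 0, 0]
        b2 = fit_glm(bold2, d1).beta_volume("Hit")[0, 0, 0]
        # joint fit with per-block intercepts on the concatenated run
        joint_trials = trials1.copy()
        shifted = trials1.copy()
        shifted["valve_open_time"] += 60 * TR
        shifted["stimulus_onset"] += 60 * TR
        shifted["trial_id"] += len(trials1)
        import pandas as pd
        joint_trials = pd.concat([joint_trials, shifted], ignore_index=True)
        joint = BOLDRun(
            data=np.concatenate([bold1.data, bold2.data], axis=3), tr=TR)
        with pytest.warns(UserWarning):
            dj = build_design(joint_trials, HRFParams(), n_volumes=120,
                              tr=TR, block_bounds=[(0, 60), (60, 120)])
        bj = fit_glm(joint, dj).beta_volume("Hit")[0, 0, 0]
        assert bj == pytest.approx((b1 + b2) / 2, abs=1e-6)


class TestSecondLevel:
    def test_identical_volumes_capped_sentinel(self):
        vol = np.full((4, 4, 3), 2.0)
        out = second_level([vol, vol, vol])
        assert (out.data == T_CAP).all()
        assert out.meta["n_degenerate"] == vol.size

    def test_type_one_rate_calibrated(self):
        # t-test calibration oracle: 10 null subjects, alpha 0.05
        rng = np.random.default_rng(8)
        n_rep = 100
        n_vox = 50
        rej = 0
        for _ in range(n_rep):
            vols = [rng.normal(0, 1, (n_vox, 1, 1)) for _ in range(10)]
            out = second_level(vols)
            p = 2 * stats.t.sf(np.abs(out.data), out.df)
            rej += (p < 0.05).sum()
        total = n_rep * n_vox
        assert abs(rej - 0.05 * total) < 3 * np.sqrt(total * 0.05 * 0.95)

    def test_group_map_localizes_common_effect(self):
        rng = np.random.default_rng(9)
        shape = (6, 6, 4)
        roi = np.zeros(shape, bool)
        roi[2:4, 2:4, 1:3] = True
        vols = []
        for _ in range(8):
            v = rng.normal(0, 0.3, shape)
            v[roi] += 1.0
            vols.append(v)
        out = second_level(vols)
        assert out.data[roi].min() > np.percentile(out.data[~roi], 99)

    def test_single_subject_rejected_and_grid_mismatch(self):
        with pytest.raises(ValueError):
            second_level([np.zeros((2, 2, 2))])
        with pytest.raises(ValueError):
            second_level([np.zeros((2, 2, 2)), np.zeros((3, 2, 2))])


class TestFdrAndConjunction:
    def _map_from_p(self, pvals, df=30):
        t = stats.t.ppf(1 - np.asarray(pvals) / 2, df)
        return StatMap(data=t.reshape(-1, 1, 1), df=df)

    def test_all_null_p_survives_nothing(self):
        out = fdr_threshold(self._map_from_p(np.full(50, 1.0)), q=0.05,
                            extent=1)
        assert out.meta["n_voxels"] == 0

    def test_bh_matches_brute_force_oracle(self):
        p = np.concatenate([np.full(10, 0.001), np.full(90, 0.5)])
        out = fdr_threshold(self._map_from_p(p), q=0.05, extent=1)
        # brute-force BH over sorted p-values
        order = np.argsort(p)
        m = len(p)
        passed = np.zeros(m, bool)
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= 0.05 * rank / m:
                k_max = rank
        passed[order[:k_max]] = True
        np.testing.assert_array_equal(out.data[:, 0, 0], passed)
        assert out.meta["n_voxels"] == 10

    def test_small_cluster_removed_by_extent(self):
        t = np.zeros((10, 10, 3))
        t[1:5, 1, 1] = 10.0       # 4-voxel line cluster
        t[6:8, 5:8, 1] = 10.0     # 6-voxel slab cluster
        out = fdr_threshold(StatMap(data=t, df=30), q=0.05, extent=5)
        assert not out.data[1:5, 1, 1].any()
        assert out.data[6:8, 5:8, 1].all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fdr_threshold(StatMap(data=np.zeros((2, 2, 2)), df=10),
                          mask=np.zeros((2, 2, 2), bool))

    def test_fdr_controlled_under_global_null(self):
        # 500-replicate all-null simulation: mean false-discovery
        # proportion stays below q + 2 MC-SE
        rng = np.random.default_rng(13)
        q = 0.05
        fdps = []
        for _ in range(500):
            t = rng.standard_t(20, size=(6, 6, 6))
            out = fdr_threshold(StatMap(data=t, df=20), q=q, extent=1)
            n_disc = out.meta["n_voxels"]
            fdps.append(1.0 if n_disc else 0.0)  # all discoveries false
        fdps = np.array(fdps)
        mc_se = fdps.std(ddof=1) / np.sqrt(len(fdps))
        assert fdps.mean() <= q + 2 * mc_se

    def test_conjunction_properties(self):
        rng = np.random.default_rng(2)
        a = StatMap(data=rng.random((5, 5, 4)) > 0.5, df=9)
        b = StatMap(data=rng.random((5, 5, 4)) > 0.5, df=9)
        ab = conjunction(a, b)
        np.testing.assert_array_equal(ab.data, a.data & b.data)
        np.testing.assert_array_equal(conjunction(a, a).data, a.data)
        disjoint = StatMap(data=~np.asarray(a.data), df=9)
        assert conjunction(a, disjoint).data.sum() == 0
        assert ab.data[~np.asarray(a.data)].sum() == 0  # subset of inputs
        with pytest.raises(ValueError):
            conjunction(a, StatMap(data=np.zeros((2, 2, 2), bool), df=9))
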