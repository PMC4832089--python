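"""Denoising operations against brute-force oracles."""

import numpy as np
import pytest

from connparc.preprocess import (framewise_displacement, dvars, scrub,
                                 friston24, tissue_pcs, bandpass,
                                 regress_nuisance, build_nuisance,
                                 ConfoundCleaner, DegenerateSeriesError)


class TestFramewiseDisplacement:
    def test_still_head_gives_zero(self):
        assert framewise_displacement(np.zeros((20, 6))).sum() == 0.0

    def test_translation_step(self):
        m = np.zeros((5, 6))
        m[3:, 0] = 0.1
        fd = framewise_displacement(m)
        assert fd[3] == pytest.approx(0.1)
        assert fd[0] == 0.0 and fd[1] == 0.0 and fd[4] == 0.0

    def test_rotation_converted_to_arc_length(self):
        m = np.zeros((4, 6))
        m[2:, 3] = 0.01
        fd = framewise_displacement(m, head_radius_mm=50)
        assert fd[2] == pytest.approx(0.01 * 50)

    def test_brute_force_oracle(self, rng):
        m = rng.normal(size=(15, 6)) * 0.1
        fd = framewise_displacement(m)
        for t in range(1, 15):
            d = m[t] - m[t - 1]
            expect = sum(abs(d[:3])) + 50 * sum(abs(d[3:]))
            assert fd[t] == pytest.approx(expect, abs=1e-12)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            framewise_displacement(np.zeros((10, 5)))


class TestDvars:
    def test_constant_series_gives_zero(self):
        ts = np.full((10, 7), 5.0)
        assert dvars(ts).sum() == 0.0

    def test_scale_invariance(self, rng):
        ts = rng.normal(size=(12, 9)) + 100
        assert np.allclose(dvars(ts), dvars(3.7 * ts))

    def test_toy_hand_computation(self):
        # 2 voxels, 3 volumes
        ts = np.array([[10.0, 20.0], [12.0, 18.0], [11.0, 21.0]])
        out = dvars(ts)
        mean = ts.mean()
        expect1 = np.sqrt((2.0 ** 2 + 2.0 ** 2) / 2) / mean * 100
        expect2 = np.sqrt((1.0 ** 2 + 3.0 ** 2) / 2) / mean * 100
        assert out[0] == 0.0
        assert out[1] == pytest.approx(expect1)
        assert out[2] == pytest.approx(expect2)

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            dvars(np.array([[1.0, -1.0], [2.0, -2.0]]))


class TestScrub:
    def test_clean_data_keeps_everything(self):
        cm = scrub(np.zeros(10), np.zeros(10))
        assert cm.keep.all()

    def test_either_criterion_censors(self):
        fd = np.array([0.0, 0.6, 0.2])
        dv = np.array([0.0, 0.0, 0.7])
        with pytest.warns(RuntimeWarning):  # only one volume survives
            cm = scrub(fd, dv)
        assert list(cm.keep) == [True, False, False]

    def test_threshold_is_strict(self):
        cm = scrub(np.full(5, 0.5), np.full(5, 0.5))
        assert cm.keep.all()

    def test_all_censored_raises(self):
        with pytest.raises(DegenerateSeriesError):
            scrub(np.full(5, 1.0), np.zeros(5))

    def test_recovers_injected_spike_frames(self):
        from connparc.phantom import default_phantom_spec, make_phantom_subject
        spec = default_phantom_spec(spike_frames=[20, 77, 140], seed=8)
        bold, masks, motion, truth = make_phantom_subject(spec, 1)
        fd = framewise_displacement(motion.to_numpy())
        dv = dvars(bold.data, masks.gm)
        cm = scrub(fd, dv)
        assert list(np.flatnonzero(~cm.keep)) == truth.spike_frames


class TestFriston24:
    def test_zero_motion_gives_zero_matrix(self):
        assert friston24(np.zeros((8, 6))).sum() == 0.0

    def test_squares_and_shift(self, rng):
        m = rng.normal(size=(10, 6))
        f = friston24(m)
        assert f.shape == (10, 24)
        assert np.allclose(f[:, 12], f[:, 0] ** 2)
        assert np.allclose(f[1:, 6], m[:-1, 0])
        assert f[0, 6:12].sum() == 0.0
        assert np.allclose(f[:, 18:], f[:, 6:12] ** 2)

    def test_ramp_example(self):
        m = np.zeros((3, 6))
        m[:, 0] = [1, 2, 3]
        f = friston24(m)
        assert list(f[:, 6]) == [0, 1, 2]
        assert list(f[:, 18]) == [0, 1, 4]


class TestTissuePcs:
    def test_rank_one_data_yields_single_dominant_component(self, rng):
        base = rng.normal(size=20)
        ts = np.outer(base, rng.normal(size=6))
        with pytest.warns(RuntimeWarning):
            pcs = tissue_pcs(ts, n_components=3)
        assert pcs.shape[1] == 1
        c = np.corrcoef(pcs[:, 0], base - base.mean())[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-10)

    def test_components_orthogonal(self, rng):
        pcs = tissue_pcs(rng.normal(size=(30, 8)), n_components=3)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_matches_svd_oracle(self, rng):
        ts = rng.normal(size=(25, 5))
        pcs = tissue_pcs(ts, n_components=3)
        c = ts - ts.mean(axis=0)
        u, s, vt = np.linalg.svd(c, full_matrices=False)
        expect = u[:, :3] * s[:3]
        for k in range(3):  # SVD columns are sign-ambiguous
            assert (np.allclose(pcs[:, k], expect[:, k], atol=1e-8)
                    or np.allclose(pcs[:, k], -expect[:, k], atol=1e-8))


class TestBandpass:
    def test_constant_series_removed(self):
        out = bandpass(np.full((100, 3), 7.0), tr=2.0)
        assert np.abs(out).max() < 1e-10

    def test_passband_amplitude_preserved(self):
        t = np.arange(300) * 2.0
        sig = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(sig[:, None], tr=2.0)[:, 0]
        mid = slice(50, 250)  # avoid filter edge transients
        assert np.abs(out[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated(self):
        t = np.arange(600) * 1.0
        sig = np.sin(2 * np.pi * 0.4 * t)
        out = bandpass(sig[:, None], tr=1.0)[:, 0]
        assert np.abs(out[100:500]).max() < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((50, 1)), high=0.3, tr=2.0)


class TestRegressNuisance:
    def test_intercept_only_demeans(self, rng):
        ts = rng.normal(size=(30, 4)) + 5
        out = regress_nuisance(ts, np.empty((30, 0)))
        assert np.allclose(out, ts - ts.mean(axis=0), atol=1e-10)

    def test_series_equal_to_confound_vanishes(self, rng):
        c = rng.normal(size=(40, 1))
        out = regress_nuisance(c.copy(), c)
        assert np.abs(out).max() < 1e-10

    def test_normal_equations_oracle(self, rng):
        ts = rng.normal(size=(50, 10))
        conf = rng.normal(size=(50, 3))
        out = regress_nuisance(ts, conf)
        x = np.column_stack([np.ones(50), conf])
        beta = np.linalg.solve(x.T @ x, x.T @ ts)
        assert np.allclose(out, ts - x @ beta, atol=1e-8)

    def test_residuals_orthogonal_to_confounds(self, rng):
        ts = rng.normal(size=(60, 5))
        conf = rng.normal(size=(60, 4))
        keep = np.ones(60, dtype=bool)
        keep[[3, 40]] = False
        out = regress_nuisance(ts, conf, keep=keep)
        assert np.abs(conf[keep].T @ out).max() < 1e-8

    def test_collinear_confounds_dropped_with_warning(self, rng):
        c1 = rng.normal(size=40)
        conf = np.column_stack([c1, 2 * c1])
        with pytest.warns(RuntimeWarning):
            out = regress_nuisance(rng.normal(size=(40, 2)), conf)
        assert out.shape == (40, 2)


class TestConfoundCleaner:
    def test_pipeline_residuals_orthogonal_on_phantom(self, small_subject):
        bold, masks, motion, truth = small_subject
        ts = bold.data[masks.gm].T
        cleaner = ConfoundCleaner(tr=bold.tr)
        cleaner.fit(ts, motion=motion.to_numpy(),
                    wm_ts=bold.data[masks.wm].T, csf_ts=bold.data[masks.csf].T)
        assert cleaner.nuisance_.matrix.shape[1] == 30
        keep = cleaner.censor_.keep
        resid = regress_nuisance(ts, cleaner.nuisance_.matrix, keep=keep)
        assert np.abs(cleaner.nuisance_.matrix[keep].T @ resid).max() < 1e-6

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone
        c = ConfoundCleaner(fd_thresh=0.3, high=0.15)
        c2 = clone(c)
        assert c2.get_params()["fd_thresh"] == 0.3
        assert c2.get_params()["high"] == 0.15

    def test_stage_order_is_recorded_and_alternative_runs(self, small_subject):
        bold, masks, motion, _ = small_subject
        ts = bold.data[masks.gm].T
        for order in ("scrub-regress-bandpass", "scrub-bandpass-regress"):
            c = ConfoundCleaner(tr=bold.tr, order=order)
            c.fit(ts, motion=motion.to_numpy())
            out = c.transform(ts)
            assert out.shape[0] == c.censor_.n_kept
            assert c.stage_log_ == order.split("-")


class TestSmooth:
    def test_preserves_total_mass(self, rng):
        from connparc.preprocess import smooth
        vol = rng.uniform(size=(12, 12, 8))
        out = smooth(vol, fwhm_mm=8.0, voxel_size=(3, 3, 3))
        # Gaussian blur conserves the (reflected-boundary) integral
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-6)
        assert out.var() < vol.var()

    def test_spatial_only_on_4d(self, rng):
        from connparc.preprocess import smooth
        vol = rng.normal(size=(8, 8, 4, 10))
        out = smooth(vol, fwhm_mm=6.0, voxel_size=3.0)
        # a temporally constant voxel stays temporally constant
        const = np.ptp(out, axis=-1)
        base = smooth(vol[..., 0], fwhm_mm=6.0, voxel_size=3.0)
        assert np.allclose(out[..., 0], base)
        assert const.shape == (8, 8, 4)
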