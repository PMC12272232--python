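"""Cleaning, smoothing and the r -> Fisher z -> across-run t chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

from pulvimap.seed_connectivity import (FWHM_TO_SD, across_run_tmap, clean_run,
                                        fisher_z, run_correlation_map,
                                        slab_seed_series, smooth_gaussian,
                                        subject_statmaps)
from pulvimap.roi_slabs import slice_mask
from pulvimap.volume_io import Image4D, ROIMask, RunData, VolumeGeometry

from conftest import DESK_ALPHA, line_mask


def _geom(dims=(6, 6, 6)):
    return VolumeGeometry(dims=dims, voxel_size_mm=(1, 1, 1),
                          affine=np.eye(4))


def _run(data, motion=None, tr=2.0):
    geom = _geom(data.shape[:3])
    T = data.shape[3]
    if motion is None:
        motion = np.random.default_rng(0).standard_normal((T, 6)) * 0.01
    img = Image4D(geometry=geom, data=data, tr_s=tr)
    return RunData(image=img, motion=motion, run_id="r0")


class TestCleanRun:
    def test_linear_ramp_projected_to_zero(self):
        T = 40
        ramp = np.linspace(0, 5, T)
        data = np.tile(ramp, (4, 4, 4, 1)) * np.arange(1, 65).reshape(4, 4, 4, 1)
        run = _run(data, motion=np.zeros((T, 6)))
        resid = clean_run(run).data
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_series_orthogonal_to_design_returned_unchanged(self):
        """A series already orthogonal to the design survives cleaning."""
        T = 50
        rng = np.random.default_rng(2)
        motion = rng.standard_normal((T, 6))
        X = np.column_stack([np.ones(T), np.arange(T), motion])
        y = rng.standard_normal(T)
        y_orth = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        data = np.tile(y_orth, (2, 2, 2, 1))
        resid = clean_run(_run(data, motion=motion)).data
        np.testing.assert_allclose(resid, data, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        """Residuals equal the hand normal-equations solution: the raw
        [1, 0..T-1, motion] design spans the same space as the internal one."""
        T = 60
        rng = np.random.default_rng(7)
        motion = rng.standard_normal((T, 6))
        data = rng.standard_normal((3, 3, 3, T))
        resid = clean_run(_run(data, motion=motion)).data
        X = np.column_stack([np.ones(T), np.arange(T, dtype=float), motion])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        for idx in np.ndindex(3, 3, 3):
            y = data[idx]
            np.testing.assert_allclose(resid[idx], y - H @ y, atol=1e-8)

    def test_residuals_mean_zero(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((3, 3, 3, 40))
        resid = clean_run(_run(data)).data
        np.testing.assert_allclose(resid.mean(axis=3), 0.0, atol=1e-10)

    def test_constant_motion_column_dropped_with_warning(self, caplog):
        T = 30
        motion = np.random.default_rng(1).standard_normal((T, 6))
        motion[:, 2] = 3.14
        data = np.random.default_rng(2).standard_normal((2, 2, 2, T))
        with caplog.at_level("WARNING", logger="pulvimap"):
            clean_run(_run(data, motion=motion))
        assert any("constant" in r.message for r in caplog.records)


class TestSmoothing:
    def test_constant_volume_invariant(self):
        img = Image4D(geometry=_geom(), data=np.full((6, 6, 6, 3), 2.5), tr_s=2)
        out = smooth_gaussian(img, 2.0)
        np.testing.assert_allclose(out.data, 2.5, atol=1e-10)

    def test_fwhm_zero_is_identity(self):
        data = np.random.default_rng(0).standard_normal((6, 6, 6, 3))
        img = Image4D(geometry=_geom(), data=data, tr_s=2)
        out = smooth_gaussian(img, 0.0)
        np.testing.assert_array_equal(out.data, data)

    def test_impulse_matches_sampled_gaussian_kernel(self):
        """A unit impulse smoothed at 2-mm FWHM reproduces the normalized
        sampled 3-D Gaussian with sd = 0.8493 mm; mass is conserved."""
        dims = (21, 21, 21)
        data = np.zeros(dims + (2,))
        data[10, 10, 10, 0] = 1.0
        img = Image4D(geometry=_geom(dims), data=data, tr_s=2)
        out = smooth_gaussian(img, 2.0).data[..., 0]
        sd = 2.0 * FWHM_TO_SD
        assert sd == pytest.approx(0.84932, abs=1e-4)
        offsets = np.arange(21) - 10.0
        w1 = np.exp(-offsets ** 2 / (2 * sd * sd))
        w1 /= w1.sum()
        expected = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
        np.testing.assert_allclose(out, expected, atol=1e-3)
        assert out.sum() == pytest.approx(1.0, abs=1e-3)

    def test_negative_fwhm_rejected(self):
        img = Image4D(geometry=_geom(), data=np.zeros((6, 6, 6, 2)), tr_s=2)
        with pytest.raises(ValueError):
            smooth_gaussian(img, -1.0)


class TestSeedSeries:
    def _labeled(self, data):
        geom = _geom(data.shape[:3])
        mask = line_mask(geom, 1, 0, data.shape[1], fixed=(2, 0, 2))
        img = Image4D(geometry=geom, data=data, tr_s=2)
        return img, slice_mask(mask, "AP", 100.0)  # one slab spanning the line

    def test_single_voxel_slab_is_that_series(self):
        geom = _geom()
        data = np.random.default_rng(0).standard_normal((6, 6, 6, 10))
        mask = line_mask(geom, 1, 3, 4, fixed=(2, 0, 2))
        lab = slice_mask(mask, "AP", 2.0)
        img = Image4D(geometry=geom, data=data, tr_s=2)
        np.testing.assert_array_equal(slab_seed_series(img, lab, 0),
                                      data[2, 3, 2])

    def test_opposite_series_cancel(self):
        data = np.zeros((6, 6, 6, 10))
        x = np.sin(np.arange(10))
        data[2, 0, 2] = x
        data[2, 1, 2] = -x
        img, lab = self._labeled(data[:, :2][:, :, :, :])
        # restrict mask to the two voxels
        geom = _geom()
        vox = np.zeros(geom.dims, dtype=bool)
        vox[2, 0, 2] = vox[2, 1, 2] = True
        lab = slice_mask(ROIMask(geometry=geom, voxels=vox), "AP", 100.0)
        img = Image4D(geometry=geom, data=data, tr_s=2)
        np.testing.assert_allclose(slab_seed_series(img, lab, 0), 0.0,
                                   atol=1e-12)

    def test_mean_oracle_on_random_slab(self):
        geom = _geom()
        rng = np.random.default_rng(5)
        data = rng.standard_normal((6, 6, 6, 12))
        vox = np.zeros(geom.dims, dtype=bool)
        flat = rng.choice(216, size=10, replace=False)
        vox[np.unravel_index(flat, geom.dims)] = True
        lab = slice_mask(ROIMask(geometry=geom, voxels=vox), "VD", 100.0)
        img = Image4D(geometry=geom, data=data, tr_s=2)
        oracle = data[vox].mean(axis=0)
        np.testing.assert_allclose(slab_seed_series(img, lab, 0), oracle,
                                   atol=1e-12)


class TestCorrelationMap:
    def _cortex(self, geom, where):
        vox = np.zeros(geom.dims, dtype=bool)
        for w in where:
            vox[w] = True
        return ROIMask(geometry=geom, voxels=vox)

    def test_identical_series_r_one(self):
        geom = _geom()
        data = np.zeros((6, 6, 6, 20))
        seed = np.random.default_rng(0).standard_normal(20)
        data[1, 1, 1] = seed
        img = Image4D(geometry=geom, data=data, tr_s=2)
        r = run_correlation_map(img, seed, self._cortex(geom, [(1, 1, 1)]))
        assert r[0] == pytest.approx(1.0)

    def test_sin_cos_orthogonal(self):
        geom = _geom()
        t = np.arange(64)
        data = np.zeros((6, 6, 6, 64))
        data[0, 0, 0] = np.sin(2 * np.pi * t / 16)
        img = Image4D(geometry=geom, data=data, tr_s=2)
        r = run_correlation_map(img, np.cos(2 * np.pi * t / 16),
                                self._cortex(geom, [(0, 0, 0)]))
        assert abs(r[0]) < 1e-6

    def test_matches_covariance_ratio_oracle(self):
        geom = _geom()
        rng = np.random.default_rng(9)
        data = rng.standard_normal((6, 6, 6, 30))
        seed = rng.standard_normal(30)
        cortex = self._cortex(geom, [(i, i, i) for i in range(6)])
        r = run_correlation_map(Image4D(geometry=geom, data=data, tr_s=2),
                                seed, cortex)
        for out, i in zip(r, range(6)):
            y = data[i, i, i]
            oracle = (np.mean(y * seed) - y.mean() * seed.mean()) / (
                y.std() * seed.std())
            assert out == pytest.approx(oracle, abs=1e-10)

    def test_zero_variance_voxel_is_missing(self):
        geom = _geom()
        data = np.zeros((6, 6, 6, 20))
        img = Image4D(geometry=geom, data=data, tr_s=2)
        r = run_correlation_map(img, np.random.default_rng(0).standard_normal(20),
                                self._cortex(geom, [(0, 0, 0)]))
        assert np.isnan(r[0])


class TestFisherZ:
    def test_fixed_points_and_closed_form(self):
        assert fisher_z(0.0) == pytest.approx(0.0)
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(-0.999, 0.999))
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(-5.0, 5.0))
    def test_tanh_inverse(self, z):
        assert fisher_z(np.tanh(z)) == pytest.approx(z, abs=1e-9)


class TestAcrossRunTmap:
    def test_three_run_example_closed_form(self):
        """z = {0.1, 0.2, 0.3}: t = 2*sqrt(3), df = 2; for df = 2 the exact
        two-sided p is 1 - t/sqrt(2 + t^2) = 0.07418 — not significant at
        0.001."""
        z = np.array([[0.1], [0.2], [0.3]])
        t, p, sig, mz = across_run_tmap(z, alpha=0.001)
        assert t[0] == pytest.approx(3.4641016, abs=1e-6)
        t_val = 2 * np.sqrt(3)
        p_exact = 1 - t_val / np.sqrt(2 + t_val ** 2)
        assert p[0] == pytest.approx(p_exact, abs=1e-9)
        assert p[0] == pytest.approx(0.07418, abs=1e-4)
        assert not sig[0]
        assert mz[0] == pytest.approx(0.2)

    def test_symmetric_z_gives_t_zero_p_one(self):
        t, p, sig, _ = across_run_tmap(np.array([[-0.4], [0.0], [0.4]]))
        assert t[0] == pytest.approx(0.0)
        assert p[0] == pytest.approx(1.0)
        assert not sig[0]

    def test_degenerate_variance_nonzero_mean_significant(self):
        t, p, sig, _ = across_run_tmap(np.array([[0.5], [0.5], [0.5]]))
        assert sig[0]
        assert p[0] == 0.0
        assert np.isinf(t[0]) and t[0] > 0

    def test_degenerate_variance_zero_mean_not_significant(self):
        t, p, sig, _ = across_run_tmap(np.zeros((3, 1)))
        assert t[0] == 0.0 and p[0] == 1.0 and not sig[0]

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            across_run_tmap(np.zeros((1, 4)))

    def test_missing_voxel_propagates(self):
        z = np.array([[0.1, np.nan], [0.2, 0.2]])
        t, p, sig, mz = across_run_tmap(z)
        assert np.isnan(t[1]) and np.isnan(p[1]) and not sig[1]


class TestSeedResolutionModes:
    def test_voxel_mode_equals_slab_mode_for_single_voxel_slabs(self):
        """When every slab contains exactly one voxel, the per-voxel-seed
        procedure and the slab-mean procedure are the same computation."""
        geom = _geom((8, 8, 8))
        rng = np.random.default_rng(21)
        data = rng.standard_normal((8, 8, 8, 40))
        runs = [_run(data), _run(rng.standard_normal((8, 8, 8, 40)))]
        vox = np.zeros(geom.dims, dtype=bool)
        vox[4, 0:6:2, 4] = True          # three 1-voxel slabs at t=2
        lab = slice_mask(ROIMask(geometry=geom, voxels=vox), "AP", 2.0,
                         hemisphere="L")
        assert lab.n_slabs == 3
        cortex = np.zeros(geom.dims, dtype=bool)
        cortex[6, :, 6] = True
        cmask = ROIMask(geometry=geom, voxels=cortex)
        s_slab = subject_statmaps(runs, lab, cmask, alpha=DESK_ALPHA,
                                  seed_resolution="slab")
        s_vox = subject_statmaps(runs, lab, cmask, alpha=DESK_ALPHA,
                                 seed_resolution="voxel")
        np.testing.assert_allclose(s_vox.mean_z, s_slab.mean_z, atol=1e-10)
        np.testing.assert_allclose(s_vox.t, s_slab.t, atol=1e-8)


class TestPipelineProperties:
    def test_scale_equivariance_of_r_z_t(self, default_cohort):
        """Scaling every time series by a positive constant leaves the whole
        r/z/t stack unchanged."""
        from pulvimap.pipeline import split_hemispheres
        _, subjects = default_cohort
        sub = subjects[0]
        seed_h = split_hemispheres(sub.seed_mask)["L"]
        cortex_h = split_hemispheres(sub.cortex_mask)["L"]
        lab = slice_mask(seed_h, "AP", 2.0, hemisphere="L")
        runs = sub.runs
        scaled = [RunData(image=Image4D(geometry=r.image.geometry,
                                        data=r.image.data * 3.7,
                                        tr_s=r.image.tr_s),
                          motion=r.motion, run_id=r.run_id) for r in runs]
        s1 = subject_statmaps(runs, lab, cortex_h, alpha=DESK_ALPHA,
                              seed_mask=sub.seed_mask)
        s2 = subject_statmaps(scaled, lab, cortex_h, alpha=DESK_ALPHA,
                              seed_mask=sub.seed_mask)
        np.testing.assert_allclose(s1.mean_z, s2.mean_z, atol=1e-8)
        np.testing.assert_allclose(s1.t, s2.t, atol=1e-6)

    def test_planted_slab_dominates_nonadjacent_slabs(self, default_cohort,
                                                      default_result):
        """On band voxels the planted slab's comparison statistic (mean z)
        exceeds every non-adjacent slab's in >= 99% of voxels at SNR 1."""
        _, subjects = default_cohort
        good = tot = 0
        for i, sub in enumerate(subjects):
            for h in ("L", "R"):
                st_ = default_result.stacks[("AP", h)][i]
                lut = {tuple(v): j for j, v in enumerate(st_.cortex_indices)}
                for (name, hh), df in sub.truth.band_assignment.items():
                    if hh != h:
                        continue
                    for row in df.itertuples():
                        j = lut.get((row.i, row.j, row.k))
                        if j is None:
                            continue
                        for k in range(st_.n_slabs):
                            if abs(k - row.slab) > 1:
                                tot += 1
                                good += (st_.mean_z[row.slab, j]
                                         > st_.mean_z[k, j])
        assert tot > 1000
        assert good / tot >= 0.99
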