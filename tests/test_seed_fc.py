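import numpy as np
import pytest

import nettdcs as nt
from nettdcs.fixtures import generate_timeseries
from nettdcs.seed_fc import (
    SeedDefinition,
    VoxelTimeSeries4D,
    check_head_motion,
    fc_map,
    mean_network_fc,
    partial_correlation,
    preprocess_timeseries,
    seed_voxels,
)


def _grid(shape=(9, 9, 9), voxel=2.0, center=(6.0, 2.0, -10.0), n_t=10, seed=0):
    """Grid whose central voxel center sits exactly at ``center`` mm."""
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = np.asarray(center) - voxel * (np.asarray(shape) // 2)
    data = np.random.default_rng(seed).standard_normal((*shape, n_t))
    return VoxelTimeSeries4D(data=data, affine=aff)


class TestSeedVoxels:
    def test_4mm_sphere_on_2mm_grid_has_33_voxels(self):
        idx = seed_voxels(SeedDefinition(), _grid())
        assert idx.shape[0] == 33

    def test_2mm_sphere_has_center_plus_face_neighbors(self):
        idx = seed_voxels(SeedDefinition(radius_mm=2.0), _grid())
        assert idx.shape[0] == 7

    def test_zero_radius_single_voxel(self):
        idx = seed_voxels(SeedDefinition(radius_mm=0.0), _grid())
        assert idx.shape[0] == 1

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            seed_voxels(SeedDefinition(center_mm=(500.0, 0.0, 0.0)), _grid())

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            SeedDefinition(radius_mm=-1.0)


class TestPreprocess:
    def _tone(self, freq_hz, n_t=400, tr=1.18):
        t = np.arange(n_t) * tr
        sig = np.sin(2 * np.pi * freq_hz * t)
        return VoxelTimeSeries4D(data=sig.reshape(1, 1, 1, -1), affine=np.eye(4), tr_s=tr)

    def test_passband_tone_preserved(self):
        ts = self._tone(0.04)
        out = preprocess_timeseries(ts)
        ratio = out.data.ravel()[50:-50].std() / ts.data.ravel()[50:-50].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_tone_attenuated(self):
        ts = self._tone(0.2)
        out = preprocess_timeseries(ts)
        ratio = out.data.ravel()[50:-50].std() / ts.data.ravel()[50:-50].std()
        assert ratio < 0.1

    def test_nuisance_regression_removes_matching_series(self, rng):
        series = rng.standard_normal(100)
        ts = VoxelTimeSeries4D(data=series.reshape(1, 1, 1, -1), affine=np.eye(4))
        # regress against the voxel's own series: residual is numerically zero
        out_ts = preprocess_timeseries(ts, nuisance=series[:, None])
        # check before filtering amplification: residual energy is ~0 relative to input
        assert np.abs(out_ts.data).max() < 1e-8 * np.abs(series).max()

    def test_rank_deficient_nuisance_warns_and_proceeds(self, rng):
        series = rng.standard_normal((1, 1, 1, 80))
        ts = VoxelTimeSeries4D(data=series, affine=np.eye(4))
        x = rng.standard_normal(80)
        X = np.column_stack([x, 2 * x])
        with pytest.warns(UserWarning, match="rank deficient"):
            preprocess_timeseries(ts, nuisance=X)

    def test_band_outside_nyquist_rejected(self):
        ts = self._tone(0.04)
        with pytest.raises(ValueError, match="band"):
            preprocess_timeseries(ts, band_hz=(0.01, 0.5))  # Nyquist ~0.424 Hz


class TestFcMap:
    def test_voxel_equal_to_seed_has_unit_correlation(self):
        ts = _grid(n_t=50)
        idx = np.array([[4, 4, 4]])
        ts.data[0, 0, 0, :] = ts.data[4, 4, 4, :]
        fc = fc_map(ts, idx)
        assert fc.r[0, 0, 0] == pytest.approx(1.0)
        assert fc.r[4, 4, 4] == pytest.approx(1.0)

    def test_anticorrelated_voxel_is_minus_one(self):
        ts = _grid(n_t=50)
        idx = np.array([[4, 4, 4]])
        ts.data[0, 0, 0, :] = -ts.data[4, 4, 4, :]
        fc = fc_map(ts, idx)
        assert fc.r[0, 0, 0] == pytest.approx(-1.0)

    def test_zero_variance_voxel_flagged_not_zeroed(self):
        ts = _grid(n_t=50)
        ts.data[1, 1, 1, :] = 7.0
        fc = fc_map(ts, np.array([[4, 4, 4]]))
        assert np.isnan(fc.r[1, 1, 1])
        assert not fc.valid[1, 1, 1]
        assert fc.valid[2, 2, 2]

    def test_null_correlation_within_sampling_band(self):
        # independent white noise at n=200: |r| < 0.139 in ~95% of replicates
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            data = rng.standard_normal((2, 1, 1, 200))
            ts = VoxelTimeSeries4D(data=data, affine=np.eye(4))
            fc = fc_map(ts, np.array([[0, 0, 0]]))
            hits += abs(fc.r[1, 0, 0]) < 0.139
        assert hits / n_rep > 0.90

    def test_planted_cluster_recovered_after_preprocessing(self):
        # r_true = 0.6 cluster, 20 seeded replicates: mean recovered r within 0.1
        recovered = []
        for s in range(20):
            ts, cluster = generate_timeseries(seed=s, r_true=0.6)
            ts = preprocess_timeseries(ts)
            idx = seed_voxels(SeedDefinition(center_mm=(0, 0, 0), radius_mm=4.0), ts)
            fc = fc_map(ts, idx)
            recovered.append(np.nanmean(fc.r[cluster]))
        assert np.mean(recovered) == pytest.approx(0.6, abs=0.1)

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError, match="seed_idx"):
            fc_map(_grid(), np.empty((0, 3), dtype=int))


class TestMeanNetworkFc:
    def test_single_voxel_mask(self, rng):
        z = rng.standard_normal((4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 2, 3] = True
        assert mean_network_fc(z, mask) == pytest.approx(z[1, 2, 3])

    def test_uniform_map_returns_constant(self):
        z = np.full((3, 3, 3), 0.42)
        mask = np.ones((3, 3, 3), dtype=bool)
        assert mean_network_fc(z, mask) == pytest.approx(0.42)

    def test_matches_loop_average_oracle(self, rng):
        z = rng.standard_normal((5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.6
        got = mean_network_fc(z, mask)
        vals = [z[i, j, k] for i, j, k in np.argwhere(mask)]
        assert got == pytest.approx(np.mean(vals), abs=1e-12)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            mean_network_fc(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestPartialCorrelation:
    def test_matches_two_stage_residual_oracle(self):
        x = np.array([3.1, 0.4, -1.2, 2.2, 0.9, -0.5, 1.7, -2.0])
        y = np.array([1.0, 0.2, -0.9, 1.8, 1.1, 0.3, 0.8, -1.4])
        cov = np.array([41.0, 55.0, 63.0, 38.0, 47.0, 52.0, 44.0, 60.0])
        r, p = partial_correlation(x, y, cov)
        X = np.column_stack([np.ones(8), cov])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        oracle = rx @ ry / (np.linalg.norm(rx) * np.linalg.norm(ry))
        assert r == pytest.approx(oracle, abs=1e-10)
        assert 0.0 <= p <= 1.0

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.standard_normal((30, 3)), columns=["x", "y", "c"])
        ref = pingouin.partial_corr(df, x="x", y="y", covar="c")
        r, p = partial_correlation(df["x"], df["y"], df["c"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)

    def test_orthogonal_covariate_equals_plain_pearson(self, rng):
        from scipy import stats

        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        cov = rng.standard_normal(40)
        # orthogonalize covariate to x, y and the intercept
        X = np.column_stack([np.ones(40), x, y])
        cov = cov - X @ np.linalg.lstsq(X, cov, rcond=None)[0]
        r, _ = partial_correlation(x, y, cov)
        assert r == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-10)

    def test_y_equal_to_covariate_gives_zero(self, rng):
        x = rng.standard_normal(20)
        cov = rng.standard_normal(20)
        r, _ = partial_correlation(x, cov, cov)
        assert abs(r) < 1e-6

    def test_symmetric_in_x_and_y(self, rng):
        x, y, cov = rng.standard_normal((3, 15))
        assert partial_correlation(x, y, cov)[0] == pytest.approx(
            partial_correlation(y, x, cov)[0], abs=1e-12
        )

    def test_invariant_to_affine_covariate_rescaling(self, rng):
        x, y, cov = rng.standard_normal((3, 15))
        r1, _ = partial_correlation(x, y, cov)
        r2, _ = partial_correlation(x, y, 3.5 * cov - 11.0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_covariate_degrades_to_pearson_with_warning(self, rng):
        from scipy import stats

        x, y = rng.standard_normal((2, 12))
        with pytest.warns(UserWarning, match="constant covariate"):
            r, _ = partial_correlation(x, y, np.full(12, 2.0))
        assert r == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            partial_correlation([1, 2, 3], [1, 2, 3], [1, 2, 4])


class TestHeadMotionCheck:
    def test_within_limits_passes(self, rng):
        m = 0.5 * rng.standard_normal((100, 6))
        assert check_head_motion(np.clip(m, -1.9, 1.9))

    def test_excessive_translation_fails(self):
        m = np.zeros((10, 6))
        m[3, 1] = 2.5
        assert not check_head_motion(m)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            check_head_motion(np.zeros((10, 5)))
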