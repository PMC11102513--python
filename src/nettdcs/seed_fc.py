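"""Seed-based resting-state functional connectivity.

The network map driving the montage is a whole-brain Pearson correlation
map against the mean time series of a small spherical seed (hypothalamus,
MNI 6, 2, -10, 4 mm radius).  Preprocessing follows the standard
resting-state pipeline subset relevant at this level: nuisance regression
(white matter, CSF, six motion parameters) by ordinary least squares,
then a zero-phase band-pass at 0.01-0.08 Hz.  Correlations are Fisher
z-transformed before averaging over network masks, and brain-behavior
associations use an age-adjusted partial correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal, stats

from .fc_target import FcMap

__all__ = [
    "SeedDefinition",
    "VoxelTimeSeries4D",
    "seed_voxels",
    "preprocess_timeseries",
    "fc_map",
    "mean_network_fc",
    "partial_correlation",
    "check_head_motion",
]

DEFAULT_TR_S = 1.18
DEFAULT_BAND_HZ = (0.01, 0.08)


@dataclass(frozen=True)
class SeedDefinition:
    """Spherical seed region in scanner (mm) coordinates."""

    center_mm: tuple[float, float, float] = (6.0, 2.0, -10.0)
    radius_mm: float = 4.0

    def __post_init__(self):
        if self.radius_mm < 0:
            raise ValueError("seed radius must be nonnegative")


@dataclass(frozen=True)
class VoxelTimeSeries4D:
    """4D voxel time series with an affine voxel-to-mm transform.

    ``data`` has shape (X, Y, Z, T); ``affine`` is the 4x4 RAS transform
    mapping 0-based voxel indices to mm coordinates.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float = DEFAULT_TR_S

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {data.shape}")
        if data.shape[3] < 3:
            raise ValueError("time series must have length >= 3")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.tr_s <= 0:
            raise ValueError("repetition time must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", aff)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def voxel_centers_mm(self) -> np.ndarray:
        """(X, Y, Z, 3) array of voxel-center mm coordinates."""
        nx, ny, nz, _ = self.data.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
        return np.einsum("ab,xyzb->xyza", self.affine, vox)[..., :3]


def seed_voxels(seed: SeedDefinition, grid: VoxelTimeSeries4D) -> np.ndarray:
    """Indices (n, 3) of voxels whose center lies within the seed sphere.

    Membership is by Euclidean distance from the voxel center to the seed
    center, boundary inclusive; on a 2 mm grid with the default 4 mm
    radius and a center on a voxel center this yields 33 voxels.
    """
    centers = grid.voxel_centers_mm()
    c = np.asarray(seed.center_mm, dtype=float)
    # center must map inside the grid
    inv = np.linalg.inv(grid.affine)
    ijk = (inv @ np.append(c, 1.0))[:3]
    if np.any(ijk < -0.5) or np.any(ijk > np.array(grid.shape[:3]) - 0.5):
        raise ValueError(f"seed center {tuple(c)} mm lies outside the voxel grid")
    d2 = np.sum((centers - c) ** 2, axis=-1)
    idx = np.argwhere(d2 <= seed.radius_mm**2 + 1e-9)
    return idx


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Remove linearly dependent columns (SVD rank test), with a warning."""
    s = np.linalg.svd(X, compute_uv=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank == X.shape[1]:
        return X
    warnings.warn(
        f"nuisance matrix is rank deficient ({rank}/{X.shape[1]}); dropping collinear columns",
        stacklevel=3,
    )
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=tol) > len(keep):
            keep.append(j)
    return X[:, keep]


def preprocess_timeseries(
    ts: VoxelTimeSeries4D,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    nuisance: np.ndarray | None = None,
) -> VoxelTimeSeries4D:
    """Demean, regress out nuisance series, and zero-phase band-pass.

    Nuisance regression is ordinary least squares per voxel (residuals
    kept); the temporal filter is a second-order Butterworth band-pass
    applied forward-backward (zero phase).  Regression precedes
    filtering, matching the conventional pipeline ordering.
    """
    low, high = band_hz
    fs = 1.0 / ts.tr_s
    nyq = fs / 2.0
    if not (0.0 <= low < high < nyq):
        raise ValueError(f"band {band_hz} Hz outside (0, Nyquist={nyq:.3f}) or inverted")

    nt = ts.n_timepoints
    Y = ts.data.reshape(-1, nt).T  # (T, V)
    Y = Y - Y.mean(axis=0, keepdims=True)

    if nuisance is not None:
        X = np.asarray(nuisance, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != nt:
            raise ValueError("nuisance regressors must match the series length")
        X = X - X.mean(axis=0, keepdims=True)
        X = _drop_collinear(X)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        Y = Y - X @ beta

    if low > 0:
        sos = signal.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    else:  # pure low-pass when the lower edge is zero
        sos = signal.butter(2, high, btype="lowpass", fs=fs, output="sos")
    Y = signal.sosfiltfilt(sos, Y, axis=0)

    return replace(ts, data=np.ascontiguousarray(Y.T.reshape(ts.shape)))


def fc_map(ts: VoxelTimeSeries4D, seed_idx: np.ndarray) -> FcMap:
    """Voxelwise Pearson correlation with the mean seed time series.

    The seed series is the mean over the seed voxels.  Voxels with zero
    temporal variance have no defined correlation; they are returned as
    NaN and marked invalid rather than silently zeroed.
    """
    seed_idx = np.asarray(seed_idx)
    if seed_idx.ndim != 2 or seed_idx.shape[0] < 1:
        raise ValueError("seed_idx must be a nonempty (n, 3) index array")
    data = ts.data
    seed_series = data[seed_idx[:, 0], seed_idx[:, 1], seed_idx[:, 2], :].mean(axis=0)
    s = seed_series - seed_series.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValueError("seed time series has zero variance")

    nt = ts.n_timepoints
    Y = data.reshape(-1, nt)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Yc, axis=1)
    valid = norms > 0
    r = np.full(Y.shape[0], np.nan)
    r[valid] = (Yc[valid] @ s) / (norms[valid] * s_norm)
    r = np.clip(r, -1.0, 1.0)
    shape3 = ts.shape[:3]
    return FcMap(
        r=r.reshape(shape3), affine=ts.affine.copy(), valid=valid.reshape(shape3)
    )


def mean_network_fc(fc_z: FcMap | np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of Fisher-z connectivity over a binary mask."""
    z = fc_z.z if isinstance(fc_z, FcMap) else np.asarray(fc_z, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != z.shape:
        raise ValueError("mask shape must match the map")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(np.mean(z[mask]))


def partial_correlation(x, y, covariate) -> tuple[float, float]:
    """Correlation of x and y after removing a covariate's linear effect.

    Both variables are residualized on [intercept, covariate] by least
    squares; r is the Pearson correlation of the residuals and p comes
    from ``t = r sqrt((n-3)/(1-r^2))`` on n-3 degrees of freedom.  A
    constant covariate degenerates to the plain correlation (warned).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    n = x.size
    if not (x.shape == y.shape == cov.shape) or x.ndim != 1:
        raise ValueError("x, y, covariate must be equal-length 1D arrays")
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    if np.ptp(cov) == 0:
        warnings.warn("constant covariate; returning plain Pearson correlation", stacklevel=2)
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    X = np.column_stack([np.ones(n), cov])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    # a variable collinear with the covariate leaves no residual variance
    # to correlate; report zero rather than amplified rounding noise
    tol_x = 1e-10 * max(np.linalg.norm(x), 1e-300)
    tol_y = 1e-10 * max(np.linalg.norm(y), 1e-300)
    if np.linalg.norm(rx) < tol_x or np.linalg.norm(ry) < tol_y:
        warnings.warn(
            "variable is collinear with the covariate; partial correlation is 0",
            stacklevel=2,
        )
        return 0.0, 1.0
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    df = n - 3
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def check_head_motion(
    motion_params: np.ndarray,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
) -> bool:
    """Validate a (T, 6) motion trace against exclusion thresholds.

    Columns 0-2 are translations (mm), 3-5 rotations (deg).  Returns True
    if the subject passes (max displacement and rotation within limits).
    """
    m = np.asarray(motion_params, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion parameters must be (T, 6)")
    trans_ok = np.all(np.abs(m[:, :3]) <= max_translation_mm)
    rot_ok = np.all(np.abs(m[:, 3:]) <= max_rotation_deg)
    return bool(trans_ok and rot_ok)
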