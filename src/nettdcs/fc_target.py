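"""From a seed functional-connectivity map to a weighted target field.

The stimulation target is specified per cortical sample as a desired
normal E-field ``t_v`` and an importance weight ``w_v``.  Polarity follows
the network sign: an excitatory ("anodal") protocol asks for field into
the cortex (+E0) where the seed correlation is positive and field out of
the cortex (-E0) where it is negative; the inhibitory ("cathodal")
protocol is the exact sign flip.  Weights grow with connectivity strength:
r >= 0.225 maps to weight 10, r <= -0.09 to weight 4, with affine
interpolation in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FcMap",
    "TargetSpec",
    "NetworkMask",
    "fisher_z",
    "weight_from_fc",
    "network_mask",
    "build_target",
    "WEIGHT_HIGH_R",
    "WEIGHT_LOW_R",
]

#: Breakpoints of the connectivity-to-weight mapping.
WEIGHT_HIGH_R = 0.225  # r at/above which weight = 10
WEIGHT_LOW_R = -0.09   # r at/below which weight = 4

#: Default mask/deadband threshold on |r|.
DEFAULT_THRESHOLD = 0.005


@dataclass(frozen=True)
class FcMap:
    """Correlation map over voxels or cortical sample points.

    ``r`` may have any shape (flat sample vector or 3D voxel grid);
    ``positions`` optionally carries sample coordinates (n, 3) for
    point-sampled maps, ``affine`` a 4x4 voxel-to-mm transform for grids.
    ``valid`` marks samples where r is defined (e.g. non-constant series).
    """

    r: np.ndarray
    positions: np.ndarray | None = None
    affine: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        ok = np.isfinite(r)
        if np.any(np.abs(r[ok]) > 1.0 + 1e-12):
            raise ValueError("correlation values must lie in [-1, 1]")
        if self.valid is not None and np.asarray(self.valid).shape != r.shape:
            raise ValueError("valid mask shape must match r")

    @property
    def z(self) -> np.ndarray:
        """Fisher-transformed map; +/-inf where |r| = 1."""
        with np.errstate(divide="ignore"):
            return np.arctanh(np.clip(self.r, -1.0, 1.0))


@dataclass(frozen=True)
class NetworkMask:
    """Binary network masks from thresholding an FC map."""

    positive: np.ndarray
    negative: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return self.positive | self.negative


@dataclass(frozen=True)
class TargetSpec:
    """Desired normal field and weight per sample."""

    t: np.ndarray  # V/m, entries in {-E0, 0, +E0}
    w: np.ndarray  # dimensionless, in [4, 10]
    polarity: str = "anodal"
    e0: float = 0.25

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        w = np.asarray(self.w, dtype=float)
        if t.shape != w.shape:
            raise ValueError("t and w must have equal shape")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "w", w)


def fisher_z(r):
    """Fisher transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires finite |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def weight_from_fc(r):
    """Map seed-connectivity strength to an optimization weight in [4, 10].

    w = 10 for r >= 0.225, w = 4 for r <= -0.09, affine in between:
    ``w = 4 + 6 (r + 0.09) / 0.315``.  Continuous and non-decreasing.
    """
    r = np.asarray(r, dtype=float)
    if np.any(~np.isfinite(r)):
        raise ValueError("weight_from_fc requires finite r")
    span = WEIGHT_HIGH_R - WEIGHT_LOW_R
    w = 4.0 + 6.0 * (r - WEIGHT_LOW_R) / span
    w = np.clip(w, 4.0, 10.0)
    return float(w) if w.ndim == 0 else w


def network_mask(
    fc: FcMap | np.ndarray,
    pos_thresh: float = DEFAULT_THRESHOLD,
    neg_thresh: float = -DEFAULT_THRESHOLD,
) -> NetworkMask:
    """Binarize an FC map into positive / negative network submasks.

    Positive submask: r > pos_thresh; negative: r < neg_thresh; the
    combined network mask is their (disjoint) union.
    """
    if not (pos_thresh > 0.0 > neg_thresh):
        raise ValueError("need pos_thresh > 0 > neg_thresh")
    r = fc.r if isinstance(fc, FcMap) else np.asarray(fc, dtype=float)
    with np.errstate(invalid="ignore"):
        pos = r > pos_thresh
        neg = r < neg_thresh
    return NetworkMask(positive=pos, negative=neg)


def build_target(
    fc: FcMap | np.ndarray,
    polarity: str = "anodal",
    e0: float = 0.25,
    deadband: float = DEFAULT_THRESHOLD,
) -> TargetSpec:
    """Turn an FC map into a weighted target normal-field specification.

    Anodal: t = +E0 where r > deadband, -E0 where r < -deadband, 0 in the
    deadband (weak-connectivity cortex is asked to stay field-free rather
    than left unconstrained).  Cathodal: every t negated.  Weights come
    from :func:`weight_from_fc` over the full sampled cortex.
    """
    if e0 <= 0:
        raise ValueError("target magnitude E0 must be positive")
    if polarity not in ("anodal", "cathodal"):
        raise ValueError("polarity must be 'anodal' or 'cathodal'")
    r = fc.r if isinstance(fc, FcMap) else np.asarray(fc, dtype=float)
    t = np.where(r > deadband, e0, np.where(r < -deadband, -e0, 0.0))
    if polarity == "cathodal":
        t = -t
    w = weight_from_fc(np.nan_to_num(r, nan=0.0))
    return TargetSpec(t=t, w=np.asarray(w, dtype=float), polarity=polarity, e0=float(e0))
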