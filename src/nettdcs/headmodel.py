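"""Concentric-sphere forward model for transcranial current stimulation.

The lead field maps per-electrode injected currents to the normal
(radial) component of the electric field at cortical sample points.  We
solve the Laplace problem for a point current source on the outer surface
of an N-layer concentric sphere analytically: in each shell the potential
is a Legendre series ``V_j(r, theta) = sum_n (A_j r^n + B_j r^-(n+1))
P_n(cos theta)``, coefficients are propagated across conductivity
interfaces by the continuity of potential and radial current density, and
the series is scaled to match the injected current density at the scalp.
The degree-0 (monopole) term is omitted: it is the only
non-charge-conserving mode and cancels exactly in any zero-sum montage,
which makes per-electrode columns well defined up to a common-mode shift
("gauge") that montage fields are invariant to.

Sign convention: cortical pyramidal cells are depolarized by field
directed *into* the cortical surface, so the normal field is reported as
``E_n = -(outward radial E)`` — positive beneath an injecting (anodal)
electrode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre

from .montage import Montage
from .positions import ElectrodePositionTable

__all__ = [
    "SphereHeadModel",
    "LeadField",
    "build_sphere_model",
    "compute_leadfield",
    "cortical_samples",
    "en_field",
    "synthetic_leadfield",
    "DEFAULT_RADII_CM",
    "DEFAULT_CONDUCTIVITIES_S_M",
]

# Standard literature 4-layer values: brain / CSF / skull / scalp.
DEFAULT_RADII_CM = (7.9, 8.1, 8.5, 9.2)
DEFAULT_CONDUCTIVITIES_S_M = (0.33, 1.79, 0.008, 0.33)
DEFAULT_TRUNCATION = 60


@dataclass(frozen=True)
class SphereHeadModel:
    """N concentric spherical shells with homogeneous conductivities.

    ``radii_cm`` are outer radii of each shell, strictly increasing from
    the innermost (brain) to the outermost (scalp) layer.
    """

    radii_cm: tuple[float, ...] = DEFAULT_RADII_CM
    conductivities_S_m: tuple[float, ...] = DEFAULT_CONDUCTIVITIES_S_M
    truncation: int = DEFAULT_TRUNCATION

    def __post_init__(self):
        r = np.asarray(self.radii_cm, dtype=float)
        s = np.asarray(self.conductivities_S_m, dtype=float)
        if r.size != s.size or r.size < 1:
            raise ValueError("radii and conductivities must be equal-length, >= 1 layer")
        if np.any(np.diff(r) <= 0) or np.any(r <= 0):
            raise ValueError("layer radii must be positive and strictly increasing outward")
        if np.any(s <= 0):
            raise ValueError("conductivities must be positive")
        if int(self.truncation) < 1:
            raise ValueError("truncation degree must be >= 1")

    @property
    def brain_radius_cm(self) -> float:
        return float(self.radii_cm[0])

    @property
    def scalp_radius_cm(self) -> float:
        return float(self.radii_cm[-1])


def build_sphere_model(
    radii_cm=DEFAULT_RADII_CM,
    conductivities_S_m=DEFAULT_CONDUCTIVITIES_S_M,
    truncation: int = DEFAULT_TRUNCATION,
) -> SphereHeadModel:
    """Validate physics parameters and return a :class:`SphereHeadModel`."""
    return SphereHeadModel(tuple(radii_cm), tuple(conductivities_S_m), int(truncation))


@dataclass(frozen=True)
class LeadField:
    """Linear map from electrode currents (mA) to normal E-field (V/m).

    ``matrix[v, e]`` is the normal field at cortical sample ``v`` per
    +1 mA injected at electrode ``e`` under the omitted-monopole reference
    convention; fields of zero-sum montages are reference-independent.
    """

    matrix: np.ndarray  # (n_samples, n_electrodes), V/m per mA
    sample_positions: np.ndarray  # (n_samples, 3) unit vectors
    labels: tuple[str, ...]
    sample_radius_cm: float = DEFAULT_RADII_CM[0]
    units: str = "V/m per mA"

    def __post_init__(self):
        if self.matrix.shape != (self.sample_positions.shape[0], len(self.labels)):
            raise ValueError("lead-field matrix shape does not match samples/labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead-field entries must be finite")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def index(self, label: str) -> int:
        for i, lab in enumerate(self.labels):
            if lab.lower() == label.lower():
                return i
        raise KeyError(f"electrode {label!r} not in lead field")


def _brain_series_coefficients(model: SphereHeadModel, n_max: int, sample_radius_cm: float) -> np.ndarray:
    """Legendre coefficients of E_n at radius ``sample_radius_cm`` per 1 mA.

    Returns ``coef`` of length ``n_max + 1`` (``coef[0] = 0``) such that
    ``E_n(gamma) = sum_n coef[n] P_n(cos gamma)`` in V/m, for a point
    electrode injecting 1 mA at the scalp surface, with the sample in the
    innermost layer.
    """
    R = model.scalp_radius_cm / 100.0  # m
    radii = np.asarray(model.radii_cm, dtype=float) / 100.0 / R  # normalized, last = 1
    sigma = np.asarray(model.conductivities_S_m, dtype=float)
    x0 = (sample_radius_cm / 100.0) / R
    current_A = 1e-3

    ns = np.arange(1, n_max + 1, dtype=float)
    # propagate (A, B) per degree across interfaces, innermost A=1, B=0
    A = np.ones_like(ns)
    B = np.zeros_like(ns)
    for j in range(len(radii) - 1):
        t = radii[j]
        u = t ** ns
        v = t ** -(ns + 1.0)
        up = ns * t ** (ns - 1.0)
        vp = -(ns + 1.0) * t ** -(ns + 2.0)
        V = A * u + B * v
        W = (sigma[j] / sigma[j + 1]) * (A * up + B * vp)
        det = u * vp - v * up  # = -(2n+1)/t^2
        A, B = (V * vp - v * W) / det, (u * W - up * V) / det
    # outer Neumann condition at x=1: sigma_N * dV/dr = j_n = I (2n+1)/(4 pi R^2)
    flux = sigma[-1] * (ns * A - (ns + 1.0) * B) / R
    scale = current_A * (2.0 * ns + 1.0) / (4.0 * np.pi * R**2) / flux
    # E_n (inward positive) = +dV/dr at the sample radius, innermost layer
    coef = np.zeros(n_max + 1)
    coef[1:] = scale * ns * x0 ** (ns - 1.0) / R
    return coef


def cortical_samples(n: int = 2000, frontal_band: bool = True, seed: int | None = None) -> np.ndarray:
    """Quasi-uniform cortical sample directions (unit vectors).

    A Fibonacci lattice on the sphere restricted to the upper hemisphere
    plus, optionally, an anterior band below the equator (the medial
    frontal / orbital cortex the appetite network extends into).
    """
    # dense full-sphere lattice, filtered to the admissible region, then
    # subsampled with an even stride so coverage stays quasi-uniform
    m = max(int(np.ceil(n * 4.0)), 256)
    i = np.arange(m) + 0.5
    z = 1.0 - 2.0 * i / m
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    keep = pts[:, 2] >= 0.0
    if frontal_band:
        keep |= (pts[:, 2] >= -0.35) & (pts[:, 1] >= 0.5)
    pts = pts[keep]
    if pts.shape[0] < n:
        raise ValueError("oversampling factor too small")  # pragma: no cover
    sel = np.linspace(0, pts.shape[0] - 1, n).astype(int)
    return pts[sel]


def compute_leadfield(
    model: SphereHeadModel,
    electrodes: ElectrodePositionTable,
    samples: np.ndarray | None = None,
    sample_radius_cm: float | None = None,
) -> LeadField:
    """Analytic lead field of the concentric-sphere model.

    Parameters
    ----------
    model:
        Head model; electrodes are point contacts on its outer surface.
    electrodes:
        Electrode direction table (unit vectors).
    samples:
        (n, 3) unit vectors of cortical sample directions; default a
        2000-point :func:`cortical_samples` lattice.
    sample_radius_cm:
        Radius of the sample shell; default the brain-layer radius.  Must
        not exceed the innermost layer radius.
    """
    if samples is None:
        samples = cortical_samples()
    samples = np.asarray(samples, dtype=float)
    if sample_radius_cm is None:
        sample_radius_cm = model.brain_radius_cm
    if sample_radius_cm > model.brain_radius_cm + 1e-12:
        raise ValueError(
            f"sample radius {sample_radius_cm} cm lies outside the innermost layer "
            f"({model.brain_radius_cm} cm)"
        )
    coef = _brain_series_coefficients(model, int(model.truncation), float(sample_radius_cm))
    cosg = np.clip(samples @ electrodes.unit_vectors.T, -1.0, 1.0)
    L = legendre.legval(cosg, coef)
    return LeadField(
        matrix=np.asarray(L, dtype=float),
        sample_positions=samples,
        labels=tuple(electrodes.labels),
        sample_radius_cm=float(sample_radius_cm),
    )


def en_field(L: LeadField, montage: Montage) -> np.ndarray:
    """Normal E-field (V/m) induced by a montage: ``L @ c`` with c in mA.

    Raises if a montage label is missing from the lead field or if the
    montage violates Kirchhoff's law (the field of a non-zero-sum current
    pattern would depend on the arbitrary reference convention).
    """
    net = montage.net_current_uA()
    if abs(net) > 1e-6:
        raise ValueError(f"montage net current {net} uA != 0; field is reference-dependent")
    c_mA = np.zeros(len(L.labels))
    for lab, cur_uA in montage.currents_uA.items():
        c_mA[L.index(lab)] += cur_uA / 1000.0
    return L.matrix @ c_mA


def synthetic_leadfield(
    electrodes: int | ElectrodePositionTable = 16,
    n_samples: int = 400,
    smoothness: float = 0.35,
    seed: int = 0,
) -> LeadField:
    """Seeded smooth random lead field for fast tests and fixtures.

    Columns are built from an exponential-in-angle kernel centered under
    each electrode (positive near field, slightly negative far field, like
    a physical normal-field pattern) modulated by seeded random amplitude
    and a few low-order random harmonics.  Entry magnitudes stay within
    O(0.01-0.5) V/m per mA.
    """
    rng = np.random.default_rng(seed)
    if isinstance(electrodes, ElectrodePositionTable):
        table = electrodes
    else:
        if int(electrodes) < 1:
            raise ValueError("need at least one electrode")
        # place synthetic electrodes on an upper-hemisphere Fibonacci lattice
        pts = cortical_samples(int(electrodes), frontal_band=False)
        table = ElectrodePositionTable(
            tuple(f"E{i + 1}" for i in range(int(electrodes))), pts
        )
    if int(n_samples) < 1:
        raise ValueError("need at least one sample")
    samples = cortical_samples(int(n_samples))
    cosg = np.clip(samples @ table.unit_vectors.T, -1.0, 1.0)
    amp = rng.uniform(0.18, 0.42, size=len(table))
    kernel = np.exp((cosg - 1.0) / smoothness) - 0.18
    wobble = np.zeros_like(cosg)
    for k in range(3):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        wobble += rng.normal(0, 0.05) * (samples @ axis)[:, None] * np.cos(
            (k + 1) * np.arccos(cosg)
        )
    L = amp[None, :] * kernel + wobble
    L = np.clip(L, -0.5, 0.5)
    return LeadField(
        matrix=L,
        sample_positions=samples,
        labels=tuple(table.labels),
        sample_radius_cm=DEFAULT_RADII_CM[0],
    )
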