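"""Standard scalp electrode positions on a unit sphere.

The 10-20 / 10-10 EEG electrode systems place electrodes at fixed fractions
of arcs measured between skull landmarks.  On an idealized spherical scalp
the construction is exact: the vertex Cz sits at inclination 0, the
nasion-inion and ear-to-ear arcs define two orthogonal great circles, the
outer "ring" (Fpz, Fp2, AF8, F8, ... Oz) lies at inclination 72 deg (10% of
the 180 deg nasion-inion arc above the equator), and intermediate
electrodes are placed at equal angular fractions along the great-circle arc
from the midline electrode of their row to the ring electrode of the same
row.  That construction is what this module implements; it yields exact
left/right mirror symmetry and reproducible coordinates without an
MRI-derived scalp surface.

Coordinate frame: right-handed RAS-like frame with +x toward the right ear,
+y toward the nasion (anterior) and +z toward the vertex.  All positions
are unit vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodePositionTable", "standard_positions", "TABLE1_LABELS"]

#: The 12 electrode labels of the published hypothalamus-network montage.
TABLE1_LABELS = (
    "P8", "F4", "C4", "FP2", "FPZ", "Fp1",
    "AF3", "Fz", "AF4", "O1", "F7", "FC5",
)

_RING_INCL_DEG = 72.0  # outer ring: 10% of the nasion-inion arc above the equator

# Longitudinal rows: midline inclination (deg from Cz; positive y = anterior)
# and the azimuth (deg from anterior midline toward the right) of the row's
# outer-ring electrode.  Azimuths step 18 deg (10% of the half-ring) per row.
_ROWS = {
    #  row   mid-incl  anterior  ring-az  ring-label-stem
    "AF": (54.0, True, 36.0, "AF"),
    "F": (36.0, True, 54.0, "F"),
    "FC": (18.0, True, 72.0, "FT"),
    "C": (0.0, True, 90.0, "T"),
    "CP": (18.0, False, 108.0, "TP"),
    "P": (36.0, False, 126.0, "P"),
    "PO": (54.0, False, 144.0, "PO"),
}

# Midline electrodes that exist outside the rows above.
_MIDLINE_EXTRA = {"Fpz": (72.0, True), "Oz": (72.0, False)}

# Ring electrodes without numbered row companions.
_RING_ONLY = {"Fp1": -18.0, "Fp2": 18.0, "O1": -162.0, "O2": 162.0}

_CLASSIC_1020 = {
    "Fp1", "Fp2", "Fpz", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2", "Oz",
}

# Interleaved 10-10 sites exposed by standard 32-channel stimulation caps.
_CAP_EXTENSIONS = {
    "AFz", "AF3", "AF4", "AF7", "AF8",
    "FC1", "FC2", "FC5", "FC6", "FT7", "FT8",
    "CP1", "CP2", "CP5", "CP6", "TP7", "TP8",
    "PO3", "PO4", "PO7", "PO8", "POz",
}


def _sph(incl_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector at inclination ``incl_deg`` from Cz, azimuth ``az_deg``
    measured from the anterior midline, positive toward the right."""
    th = np.deg2rad(incl_deg)
    ph = np.deg2rad(az_deg)
    return np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, f: float) -> np.ndarray:
    """Point at fraction ``f`` along the great-circle arc from ``a`` to ``b``."""
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - f) * omega) * a + np.sin(f * omega) * b) / np.sin(omega)


def _build_1010() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {"Cz": _sph(0.0, 0.0)}
    for label, (incl, anterior) in _MIDLINE_EXTRA.items():
        pos[label] = _sph(incl, 0.0 if anterior else 180.0)
    for label, az in _RING_ONLY.items():
        pos[label] = _sph(_RING_INCL_DEG, az)
    for row, (mid_incl, anterior, ring_az, ring_stem) in _ROWS.items():
        mid_az = 0.0 if anterior else 180.0
        mid = _sph(mid_incl, mid_az)
        if row != "C":
            pos[row + "z"] = mid
        for side, sgn in (("left", -1), ("right", +1)):
            ring = _sph(_RING_INCL_DEG, sgn * ring_az)
            ring_label = f"{ring_stem}{7 if sgn < 0 else 8}"
            pos[ring_label] = ring
            for k, frac in ((1, 0.25), (3, 0.5), (5, 0.75)):
                num = k if sgn < 0 else k + 1
                pos[f"{row}{num}"] = _slerp(mid, ring, frac)
    # normalize (slerp already unit, but guard against rounding)
    return {k: v / np.linalg.norm(v) for k, v in pos.items()}


@dataclass(frozen=True)
class ElectrodePositionTable:
    """Labeled unit-vector electrode positions on a spherical scalp.

    Labels are matched case-insensitively throughout the package (published
    montage tables mix spellings such as "FP2" and "Fp1").
    """

    labels: tuple[str, ...]
    unit_vectors: np.ndarray  # (n, 3), unit norm
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.labels) != self.unit_vectors.shape[0]:
            raise ValueError("labels and unit_vectors length mismatch")
        idx = {}
        for i, lab in enumerate(self.labels):
            key = lab.lower()
            if key in idx:
                raise ValueError(f"duplicate electrode label {lab!r}")
            idx[key] = i
        norms = np.linalg.norm(self.unit_vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("electrode position vectors must be unit norm")
        object.__setattr__(self, "_index", idx)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label.lower() in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label.lower()]
        except KeyError:
            raise KeyError(f"unknown electrode label {label!r}") from None

    def position(self, label: str) -> np.ndarray:
        return self.unit_vectors[self.index(label)]

    def positions_for(self, labels) -> np.ndarray:
        return self.unit_vectors[[self.index(l) for l in labels]]

    def inclination_deg(self, label: str) -> float:
        """Angle from the vertex (Cz) in degrees."""
        return float(np.rad2deg(np.arccos(np.clip(self.position(label)[2], -1, 1))))

    def subset(self, labels) -> "ElectrodePositionTable":
        labels = tuple(labels)
        return ElectrodePositionTable(labels, self.positions_for(labels))


def standard_positions(system: str = "10-20") -> ElectrodePositionTable:
    """Return the standard electrode table for a montage system.

    Parameters
    ----------
    system:
        ``"10-10"`` for the full combinatorial 10-10 grid, or ``"10-20"``
        for the classic 21 sites plus the interleaved 10-10 sites that
        standard 32-channel stimulation caps expose (the published
        12-electrode montage uses several of these, e.g. AF3, AF4, FC5).

    Raises
    ------
    ValueError
        If ``system`` is not one of the known identifiers.
    """
    key = system.strip().lower().replace("_", "-")
    grid = _build_1010()
    if key in ("10-10", "1010"):
        wanted = set(grid)
    elif key in ("10-20", "1020"):
        wanted = _CLASSIC_1020 | _CAP_EXTENSIONS
    else:
        raise ValueError(f"unknown electrode system {system!r}; expected '10-20' or '10-10'")
    labels = tuple(sorted(wanted, key=str.lower))
    return ElectrodePositionTable(labels, np.array([grid[l] for l in labels]))
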