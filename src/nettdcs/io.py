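"""File I/O: NIfTI volumes, montage tables, lead fields, session logs,
flat key=value configs and run manifests.

Tabular outputs are plain CSV with a header row and '.' decimal; volumes
are NIfTI-1 via nibabel; lead fields are stored as a CSV matrix plus a
JSON sidecar carrying labels, sample coordinates and units.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fc_target import FcMap
from .headmodel import LeadField
from .montage import Montage, current_density, invert_polarity
from .optimizer import OptimizationResult
from .seed_fc import VoxelTimeSeries4D
from .sst import SstSession

__all__ = [
    "read_fc_volume",
    "write_fc_volume",
    "read_timeseries",
    "write_timeseries",
    "write_montage_table",
    "read_montage_table",
    "save_leadfield",
    "load_leadfield",
    "write_session_log",
    "read_session_log",
    "read_flat_config",
    "write_manifest",
]

logger = logging.getLogger("nettdcs")


def read_fc_volume(path) -> FcMap:
    """Load a 3D correlation volume.

    Non-finite voxels are masked out (count logged); values outside
    [-1, 1] are clamped with a warning (correlation maps occasionally
    carry rounding overshoot).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D {data.shape}")
    valid = np.isfinite(data)
    n_bad = int(valid.size - valid.sum())
    if n_bad:
        logger.info("masked %d non-finite voxels in %s", n_bad, path)
    out = np.where(valid, data, np.nan)
    over = valid & (np.abs(out) > 1.0)
    if over.any():
        warnings.warn(
            f"{int(over.sum())} voxels outside [-1, 1]; clamping", stacklevel=2
        )
        out = np.clip(out, -1.0, 1.0)
    return FcMap(r=out, affine=np.asarray(img.affine), valid=valid)


def write_fc_volume(fc: FcMap, path) -> Path:
    aff = fc.affine if fc.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(fc.r, dtype=np.float64), aff), str(path))
    return Path(path)


def read_timeseries(path, tr_s: float | None = None) -> VoxelTimeSeries4D:
    """Load a 4D NIfTI series; TR from the header unless overridden."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D series, got {data.ndim}D {data.shape}")
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3]) or 1.18
    return VoxelTimeSeries4D(data=data, affine=np.asarray(img.affine), tr_s=tr_s)


def write_timeseries(ts: VoxelTimeSeries4D, path) -> Path:
    img = nib.Nifti1Image(np.asarray(ts.data, dtype=np.float64), ts.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (ts.tr_s,))
    nib.save(img, str(path))
    return Path(path)


def write_montage_table(result: OptimizationResult | Montage, path) -> Path:
    """Write a montage and its polarity-inverted twin as CSV.

    Columns: polarity, electrode_label, current_uA, current_density_mA_cm2.
    The file is losslessly re-readable with :func:`read_montage_table`.
    """
    montage = result.montage if isinstance(result, OptimizationResult) else result
    twin = invert_polarity(montage)
    rows = []
    for m in (montage, twin):
        dens = current_density(m)
        for lab in m.labels:
            rows.append(
                dict(
                    polarity=m.polarity,
                    electrode_label=lab,
                    current_uA=m.currents_uA[lab],
                    current_density_mA_cm2=dens[lab],
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_montage_table(path) -> dict[str, Montage]:
    """Read a montage CSV back into one Montage per polarity block."""
    df = pd.read_csv(path)
    out: dict[str, Montage] = {}
    for pol, grp in df.groupby("polarity", sort=False):
        out[pol] = Montage(
            currents_uA=dict(zip(grp["electrode_label"], grp["current_uA"].astype(float))),
            polarity=str(pol),
        )
    return out


def save_leadfield(L: LeadField, prefix) -> tuple[Path, Path]:
    """Persist a lead field as ``<prefix>_matrix.csv`` + ``<prefix>_meta.json``.

    The matrix CSV has one electrode per column (labeled header) and one
    sample per row; the sidecar stores sample coordinates, the sample
    shell radius and units.
    """
    prefix = Path(prefix)
    mat_path = prefix.with_name(prefix.name + "_matrix.csv")
    meta_path = prefix.with_name(prefix.name + "_meta.json")
    pd.DataFrame(L.matrix, columns=list(L.labels)).to_csv(mat_path, index=False)
    meta = {
        "labels": list(L.labels),
        "sample_positions": L.sample_positions.tolist(),
        "sample_radius_cm": L.sample_radius_cm,
        "units": L.units,
    }
    meta_path.write_text(json.dumps(meta))
    return mat_path, meta_path


def load_leadfield(prefix) -> LeadField:
    prefix = Path(prefix)
    mat = pd.read_csv(prefix.with_name(prefix.name + "_matrix.csv"))
    meta = json.loads(prefix.with_name(prefix.name + "_meta.json").read_text())
    return LeadField(
        matrix=mat.to_numpy(dtype=float),
        sample_positions=np.asarray(meta["sample_positions"], dtype=float),
        labels=tuple(meta["labels"]),
        sample_radius_cm=float(meta["sample_radius_cm"]),
        units=str(meta["units"]),
    )


def write_session_log(session: SstSession, path) -> Path:
    """Per-trial session log as CSV (trial, type, ssd_ms, rt_ms, outcome)."""
    session.trials.to_csv(path, index=False)
    return Path(path)


def read_session_log(path) -> SstSession:
    df = pd.read_csv(path)
    required = {"trial", "practice", "type", "ssd_ms", "rt_ms", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"session log missing columns: {sorted(missing)}")
    stair = df.loc[df["type"] == "stop", "ssd_ms"].to_numpy()
    return SstSession(trials=df, staircase=stair)


def read_flat_config(path) -> dict[str, str]:
    """Parse a flat ``key = value`` text config; '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out


def write_manifest(path, *, inputs: dict, seed: int | None = None) -> Path:
    """Machine-readable run manifest (inputs, seed, package version)."""
    from . import __version__

    manifest = {"package": "nettdcs", "version": __version__, "seed": seed, "inputs": inputs}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return Path(path)
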