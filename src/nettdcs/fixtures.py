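"""Synthetic study fixtures.

The real study inputs (a Neurosynth hypothalamus co-activation map, ten
participants' resting-state scans, and touchscreen stop-signal logs) are
not redistributable, so every workflow in this package is exercised on
seeded synthetic stand-ins that emulate their statistical structure:

* a smooth functional-connectivity field with a positive medial-frontal
  cluster (r up to ~0.3) and negative dorsolateral / deep clusters
  (r down to ~-0.2), so all three weight regimes (w = 4, 4 < w < 10,
  w = 10) and the +/-0.005 mask thresholds are exercised;
* 4D voxel time series with a planted seed-correlated cluster whose
  signals are band-limited to the analysis band, so the planted
  correlation survives preprocessing;
* race-model stop-signal sessions for a 3-condition x N-subject
  crossover with a configurable anodal effect on the stop latency;
* a seeded synthetic lead field over the standard electrode table.

All randomness flows through explicit integer seeds; the same seed
reproduces the same bundle bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .fc_target import FcMap
from .headmodel import LeadField, synthetic_leadfield
from .positions import standard_positions
from .seed_fc import DEFAULT_TR_S, SeedDefinition, VoxelTimeSeries4D
from .sst import RaceAgentParams, SstSession, make_schedule, simulate_session

__all__ = [
    "FixtureStudy",
    "generate_fc_volume",
    "generate_fc_on_cortex",
    "generate_timeseries",
    "generate_sst_study",
    "generate_fixture_study",
]

# Cluster geometry in mm, loosely MNI-like: +y anterior, +z superior.
# The positive cluster abuts the frontal pole so the cortical surface
# (r ~ 79 mm) passes through its core.
_POS_CLUSTER_MM = (0.0, 66.0, -4.0)     # medial frontal / orbital
_NEG_CLUSTERS_MM = ((-42.0, 38.0, 22.0), (42.0, 38.0, 22.0), (-22.0, 8.0, 2.0), (22.0, 8.0, 2.0))
_POS_AMPLITUDE = 0.32
_NEG_AMPLITUDE = 0.22
_CLUSTER_SCALE_MM = 24.0


def _fc_field(points_mm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth synthetic seed-FC field evaluated at mm coordinates."""

    def blob(center, scale=_CLUSTER_SCALE_MM):
        d2 = np.sum((points_mm - np.asarray(center)) ** 2, axis=-1)
        return np.exp(-d2 / (2.0 * scale**2))

    r = _POS_AMPLITUDE * blob(_POS_CLUSTER_MM)
    for c in _NEG_CLUSTERS_MM:
        r -= _NEG_AMPLITUDE * blob(c, scale=18.0)
    # low-amplitude smooth background so values straddle the +/-0.005
    # mask thresholds rather than sitting at exact zero
    for _ in range(6):
        center = rng.uniform(-60, 60, size=3)
        r += rng.normal(0.0, 0.012) * blob(center, scale=30.0)
    return np.clip(r, -0.95, 0.95)


def _default_affine(shape, voxel_mm=6.0):
    """Grid centered on the origin with isotropic voxels (RAS)."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(shape, dtype=float) - 1) / 2.0
    return aff


def generate_fc_volume(seed: int = 0, shape=(24, 28, 22), voxel_mm: float = 6.0) -> FcMap:
    """Seeded smooth FC volume with the cluster layout described above."""
    rng = np.random.default_rng(seed)
    aff = _default_affine(shape, voxel_mm)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    mm = np.einsum("ab,xyzb->xyza", aff, vox)[..., :3]
    r = _fc_field(mm.reshape(-1, 3), rng).reshape(shape)
    return FcMap(r=r, affine=aff)


def generate_fc_on_cortex(L: LeadField, seed: int = 0, cortex_radius_mm: float = 79.0) -> FcMap:
    """The same smooth FC field sampled at a lead field's cortical points."""
    rng = np.random.default_rng(seed)
    pts_mm = L.sample_positions * cortex_radius_mm
    return FcMap(r=_fc_field(pts_mm, rng), positions=L.sample_positions.copy())


def _band_limited(rng, n_series, n_t, tr_s, band=(0.01, 0.08)):
    """Unit-variance noise restricted to the analysis band."""
    x = rng.standard_normal((n_series, n_t))
    sos = signal.butter(2, band, btype="bandpass", fs=1.0 / tr_s, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_timeseries(
    seed: int = 0,
    shape=(12, 12, 10),
    n_timepoints: int = 200,
    tr_s: float = DEFAULT_TR_S,
    voxel_mm: float = 2.0,
    seed_region: SeedDefinition | None = None,
    cluster_center_mm=(0.0, 9.0, 0.0),
    cluster_radius_mm: float = 5.0,
    r_true: float = 0.6,
) -> tuple[VoxelTimeSeries4D, np.ndarray]:
    """4D series with a cluster correlated to the seed region at ``r_true``.

    The seed-region voxels carry a shared band-limited signal; cluster
    voxels mix that signal with independent band-limited noise at
    ``r_true``.  Because every component lives inside the analysis band,
    the planted correlation is preserved by preprocessing.  Returns the
    series and a boolean cluster mask.
    """
    if seed_region is None:
        # grid is centered on the origin; put the seed at its center
        seed_region = SeedDefinition(center_mm=(0.0, 0.0, 0.0), radius_mm=4.0)
    rng = np.random.default_rng(seed)
    aff = _default_affine(shape, voxel_mm)
    nvox = int(np.prod(shape))
    noise = _band_limited(rng, nvox, n_timepoints, tr_s)
    s = _band_limited(rng, 1, n_timepoints, tr_s)[0]

    data = noise.reshape(*shape, n_timepoints).copy()
    ts = VoxelTimeSeries4D(data=data, affine=aff, tr_s=tr_s)
    centers = ts.voxel_centers_mm()

    seed_d2 = np.sum((centers - np.asarray(seed_region.center_mm)) ** 2, axis=-1)
    in_seed = seed_d2 <= seed_region.radius_mm**2 + 1e-9
    clus_d2 = np.sum((centers - np.asarray(cluster_center_mm)) ** 2, axis=-1)
    in_cluster = (clus_d2 <= cluster_radius_mm**2 + 1e-9) & ~in_seed

    mix = r_true * s[None, :] + np.sqrt(1.0 - r_true**2) * data[in_cluster]
    data[in_cluster] = mix
    data[in_seed] = s[None, :] + 0.05 * data[in_seed]
    return VoxelTimeSeries4D(data=data, affine=aff, tr_s=tr_s), in_cluster


def generate_sst_study(
    seed: int = 0,
    n_subjects: int = 10,
    anodal_effect_ms: float = -15.0,
    cathodal_effect_ms: float = 0.0,
    subject_sd_ms: float = 15.0,
    base_agent: RaceAgentParams = RaceAgentParams(),
) -> dict[tuple[int, str], SstSession]:
    """Crossover stop-signal dataset: anodal / cathodal / sham per subject.

    Condition effects shift the subject's true stop latency; the anodal
    default of -15 ms mirrors a plausible facilitation magnitude.
    Returns ``{(subject, condition): session}``.
    """
    root = np.random.SeedSequence(seed)
    subj_seeds = root.spawn(n_subjects)
    effects = {"sham": 0.0, "anodal": anodal_effect_ms, "cathodal": cathodal_effect_ms}
    sessions: dict[tuple[int, str], SstSession] = {}
    for s, subj_ss in enumerate(subj_seeds):
        offs_rng = np.random.default_rng(subj_ss)
        subj_offset = offs_rng.normal(0.0, subject_sd_ms)
        cond_seeds = subj_ss.spawn(2 * len(effects))
        for k, (cond, eff) in enumerate(effects.items()):
            agent = RaceAgentParams(
                go_mu_ms=base_agent.go_mu_ms,
                go_sigma_ms=base_agent.go_sigma_ms,
                go_tau_ms=base_agent.go_tau_ms,
                stop_mu_ms=base_agent.stop_mu_ms + subj_offset + eff,
                stop_sigma_ms=base_agent.stop_sigma_ms,
                omission_rate=base_agent.omission_rate,
            )
            sched_rng = np.random.default_rng(cond_seeds[2 * k])
            sess_rng = np.random.default_rng(cond_seeds[2 * k + 1])
            schedule = make_schedule(seed=int(sched_rng.integers(2**31 - 1)))
            sessions[(s, cond)] = simulate_session(
                schedule, agent, seed=int(sess_rng.integers(2**31 - 1))
            )
    return sessions


@dataclass(frozen=True)
class FixtureStudy:
    """A full synthetic study bundle (see :func:`generate_fixture_study`)."""

    fc_volume: FcMap
    timeseries: VoxelTimeSeries4D
    cluster_mask: np.ndarray
    leadfield: LeadField
    fc_on_cortex: FcMap
    sst_sessions: dict[tuple[int, str], SstSession]
    seed: int


def generate_fixture_study(
    seed: int = 0,
    n_subjects: int = 10,
    n_leadfield_samples: int = 400,
    anodal_effect_ms: float = -15.0,
) -> FixtureStudy:
    """Generate the complete seeded synthetic study bundle.

    Sub-seeds for each component are derived deterministically from
    ``seed``, so equal seeds give identical bundles.
    """
    ss = np.random.SeedSequence(seed)
    s_fc, s_ts, s_lf, s_cortex, s_sst = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(5))
    L = synthetic_leadfield(standard_positions("10-20"), n_samples=n_leadfield_samples, seed=s_lf)
    ts, cluster = generate_timeseries(seed=s_ts)
    return FixtureStudy(
        fc_volume=generate_fc_volume(seed=s_fc),
        timeseries=ts,
        cluster_mask=cluster,
        leadfield=L,
        fc_on_cortex=generate_fc_on_cortex(L, seed=s_cortex),
        sst_sessions=generate_sst_study(
            seed=s_sst, n_subjects=n_subjects, anodal_effect_ms=anodal_effect_ms
        ),
        seed=int(seed),
    )
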