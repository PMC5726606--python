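"""Probabilistic streamline propagation from grey–white interface seeds.

Streamlines step through the phantom's per-voxel orientation field at a fixed
step size, sampling a direction at every step from the voxel's orientation
distribution (the principal direction perturbed by a half-normal angular
deviation about a uniformly random perpendicular axis).  Directions are
sign-aligned with the previous step to prevent spurious reversals; the first
step explores both signs of the fibre axis with equal probability.

A streamline stops when it enters the exclusion mask (everything outside the
white matter — the stopping point *is* retained, since terminations on grey
matter are the quantity of interest), when its path length would exceed the
length cap, or when its direction change over one voxel-length of arc exceeds
the curvature limit.  At the default 180° limit the curvature rule only
forbids exact reversals.

The batch engine propagates many streamlines in lock-step with NumPy; the
single-streamline API is a thin wrapper over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import check_same_grid, VolumeGrid
from .phantom import Phantom

STOP_EXCLUSION = "exclusion_mask"
STOP_MAX_LENGTH = "max_length"
STOP_CURVATURE = "curvature"
_REASONS = (STOP_EXCLUSION, STOP_MAX_LENGTH, STOP_CURVATURE)


@dataclass(frozen=True)
class TrackingParams:
    """Propagation parameters (defaults follow the study protocol:
    10,000 streamlines per seed, 0.5 mm steps, 500 mm length cap, 180°
    curvature limit over one voxel of arc)."""

    n_streamlines: int = 10_000
    step_mm: float = 0.5
    max_length_mm: float = 500.0
    curvature_limit_deg: float = 180.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_streamlines <= 0 or self.step_mm <= 0 or self.max_length_mm <= 0:
            raise ValueError("counts, step and length cap must be positive")
        if not (0.0 < self.curvature_limit_deg <= 180.0):
            raise ValueError("curvature_limit_deg must be in (0, 180]")


@dataclass
class Streamline:
    points: np.ndarray  # (k, 3) world mm
    seed_voxel: tuple[int, int, int]
    reason: str

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class SeedConnectivity:
    """Per-seed visitation counts: how many of the seed's streamlines visited
    each voxel (each streamline counts at most once per voxel)."""

    seed_voxel: tuple[int, int, int]
    counts: np.ndarray  # integer volume
    n_streamlines: int


@dataclass
class BatchResult:
    """Vectorised propagation output for one batch of streamlines."""

    reasons: np.ndarray                 # (n,) of _REASONS strings
    n_points: np.ndarray                # (n,) points per streamline
    roi_hits: np.ndarray                # (n, n_rois) bool
    visit_streams: np.ndarray | None    # unique (stream, voxel) pairs
    visit_voxels: np.ndarray | None     # flat voxel indices, aligned with above
    paths: list[np.ndarray] | None


# ---------------------------------------------------------------------------
# direction sampling


def _perpendicular_basis(dirs: np.ndarray):
    helper = np.zeros_like(dirs)
    use_x = np.abs(dirs[:, 0]) < 0.9
    helper[use_x, 0] = 1.0
    helper[~use_x, 1] = 1.0
    e1 = np.cross(dirs, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(dirs, e1)
    return e1, e2


def _perturb(dirs: np.ndarray, dispersion_deg: float,
             rng: np.random.Generator) -> np.ndarray:
    """Deflect each unit vector by a half-normal angle (SD = dispersion) about
    a uniformly random axis perpendicular to it."""
    if dispersion_deg == 0:
        return dirs
    m = dirs.shape[0]
    theta = np.abs(rng.normal(0.0, np.deg2rad(dispersion_deg), size=m))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=m)
    e1, e2 = _perpendicular_basis(dirs)
    w = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
    return np.cos(theta)[:, None] * dirs + np.sin(theta)[:, None] * w


def sample_direction(field_direction: np.ndarray,
                     previous_direction: np.ndarray | None,
                     dispersion_deg: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw one propagation direction at a point of the orientation field.

    The fibre axis is sign-ambiguous: with a previous direction the axis is
    flipped so their dot product is >= 0; on the first step the sign is chosen
    uniformly at random.
    """
    d = np.asarray(field_direction, dtype=float)
    if not np.isfinite(d).all() or np.linalg.norm(d) == 0:
        raise ValueError("point outside the orientation field")
    d = d / np.linalg.norm(d)
    if previous_direction is None:
        d = d * (1.0 if rng.random() < 0.5 else -1.0)
    elif np.dot(d, previous_direction) < 0:
        d = -d
    out = _perturb(d[None, :], dispersion_deg, rng)[0]
    if previous_direction is not None and np.dot(out, previous_direction) < 0:
        out = -out
    return out


# ---------------------------------------------------------------------------
# batch propagation


def propagate_streamlines(start_points: np.ndarray,
                          phantom: Phantom,
                          params: TrackingParams,
                          rng: np.random.Generator,
                          roi_masks: tuple[np.ndarray, ...] = (),
                          record_paths: bool = False,
                          record_visits: bool = False) -> BatchResult:
    """Propagate one batch of streamlines in lock-step.

    All streamlines share the step schedule, so the arc length after ``t``
    steps is ``t * step_mm`` for every active streamline.  Streamlines whose
    start point is not inside the white matter stop immediately with the
    exclusion reason.
    """
    grid = phantom.grid
    wm = phantom.wm_mask
    field = phantom.orientation_field.reshape(-1, 3)
    wm_flat = wm.ravel()
    roi_flat = [np.asarray(r, dtype=bool).ravel() for r in roi_masks]
    shape = grid.shape
    n = int(start_points.shape[0])
    step = params.step_mm
    max_steps = int(np.floor(params.max_length_mm / step + 1e-9))
    k_hist = max(int(np.ceil(grid.voxel_size / step - 1e-9)), 1)
    cos_limit = np.cos(np.deg2rad(params.curvature_limit_deg))

    reasons = np.full(n, -1, dtype=np.int8)
    n_points = np.ones(n, dtype=np.int64)
    hits = np.zeros((n, len(roi_flat)), dtype=bool)
    visit_chunks: list[np.ndarray] = []
    visit_ids: list[np.ndarray] = []

    pos = np.asarray(start_points, dtype=float).copy()
    gid = np.arange(n)

    def flat_of(points):
        vox = grid.world_to_voxel(points)
        ok = grid.inside(vox)
        flat = np.full(len(points), -1, dtype=np.int64)
        if ok.any():
            v = vox[ok]
            flat[ok] = np.ravel_multi_index((v[:, 0], v[:, 1], v[:, 2]), shape)
        return flat, ok

    def record(ids, points):
        flat, ok = flat_of(points)
        if record_visits and ok.any():
            visit_ids.append(ids[ok])
            visit_chunks.append(flat[ok])
        for j, r in enumerate(roi_flat):
            sel = ok & r[np.where(ok, flat, 0)] if ok.any() else ok
            hits[ids[sel], j] = True
        return flat, ok

    # the seed point itself is a recorded point of every streamline
    flat0, ok0 = record(gid, pos)
    point_log: list[tuple[np.ndarray, np.ndarray]] = []
    if record_paths:
        point_log.append((gid.copy(), pos.copy()))

    in_wm0 = ok0 & wm_flat[np.where(ok0, flat0, 0)]
    dead = ~in_wm0
    reasons[gid[dead]] = 0  # exclusion immediately
    keep = ~dead
    gid, pos = gid[keep], pos[keep]

    prev = np.zeros((len(gid), 3))
    hist = np.zeros((k_hist, n, 3))  # indexed by global id to survive compaction

    t = 0
    while len(gid) and t < max_steps:
        flat, _ = flat_of(pos)  # all alive are inside WM, hence inside grid
        fdir = field[flat]
        if t == 0:
            sign = np.where(rng.random(len(gid)) < 0.5, 1.0, -1.0)
        else:
            dots = np.einsum("ij,ij->i", fdir, prev)
            sign = np.where(dots < 0, -1.0, 1.0)
        dirs = _perturb(fdir * sign[:, None], phantom.dispersion_deg, rng)
        if t > 0:
            flip = np.einsum("ij,ij->i", dirs, prev) < 0
            dirs[flip] *= -1.0

        if t >= k_hist and cos_limit > -1.0 + 1e-12:
            old = hist[t % k_hist, gid]
            bend = np.einsum("ij,ij->i", dirs, old) < cos_limit
            if bend.any():
                reasons[gid[bend]] = 2  # curvature: stop before stepping
                keepb = ~bend
                gid, pos, dirs = gid[keepb], pos[keepb], dirs[keepb]
                if not len(gid):
                    break
        hist[t % k_hist, gid] = dirs

        pos = pos + step * dirs
        n_points[gid] += 1
        if record_paths:
            point_log.append((gid.copy(), pos.copy()))
        flat, ok = record(gid, pos)

        in_wm = ok & wm_flat[np.where(ok, flat, 0)]
        stopped = ~in_wm
        reasons[gid[stopped]] = 0  # entered exclusion mask (point retained)
        gid, pos, prev = gid[in_wm], pos[in_wm], dirs[in_wm]
        t += 1

    reasons[gid[reasons[gid] == -1]] = 1  # survivors hit the length cap
    reasons[reasons == -1] = 0  # safety; should not occur

    visit_streams = visit_voxels = None
    if record_visits:
        ids = np.concatenate(visit_ids) if visit_ids else np.empty(0, np.int64)
        vox = np.concatenate(visit_chunks) if visit_chunks else np.empty(0, np.int64)
        n_flat = int(np.prod(shape))
        key = ids.astype(np.int64) * n_flat + vox
        key = np.unique(key)
        visit_streams = key // n_flat
        visit_voxels = key % n_flat

    out_paths = None
    if record_paths:
        buf: list[list[np.ndarray]] = [[] for _ in range(n)]
        for ids, points in point_log:
            for i, p in zip(ids, points):
                buf[i].append(p)
        out_paths = [np.asarray(b) for b in buf]

    return BatchResult(
        reasons=np.asarray(_REASONS)[reasons],
        n_points=n_points,
        roi_hits=hits,
        visit_streams=visit_streams,
        visit_voxels=visit_voxels,
        paths=out_paths,
    )


# ---------------------------------------------------------------------------
# per-seed API


def seed_rng(params: TrackingParams, subject: int,
             seed_voxel_flat: int) -> np.random.Generator:
    """RNG for one seed voxel, split hierarchically from the global seed so any
    single seed's streamlines are reproducible in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence((int(params.rng_seed), int(subject),
                                int(seed_voxel_flat))))


def propagate_streamline(seed_point: np.ndarray, phantom: Phantom,
                         params: TrackingParams,
                         rng: np.random.Generator) -> Streamline:
    """Propagate a single streamline from a world-mm point."""
    res = propagate_streamlines(np.asarray(seed_point, float)[None, :],
                                phantom, params, rng, record_paths=True)
    vox = tuple(int(v) for v in phantom.grid.world_to_voxel(seed_point))
    return Streamline(points=res.paths[0], seed_voxel=vox,
                      reason=str(res.reasons[0]))


def track_seed(seed_voxel, phantom: Phantom, params: TrackingParams,
               rng: np.random.Generator | None = None,
               roi_masks: tuple[np.ndarray, ...] = (),
               keep_streamlines: bool = True):
    """Launch ``params.n_streamlines`` streamlines from a seed voxel centre.

    Returns ``(SeedConnectivity, streamlines, roi_hits)``; a streamline
    increments a voxel's count at most once however often it re-enters.
    """
    grid = phantom.grid
    seed_voxel = tuple(int(v) for v in seed_voxel)
    flat = int(np.ravel_multi_index(seed_voxel, grid.shape))
    if rng is None:
        rng = seed_rng(params, 0, flat)
    centre = grid.voxel_to_world(np.asarray(seed_voxel, float))
    starts = np.tile(centre, (params.n_streamlines, 1))
    res = propagate_streamlines(starts, phantom, params, rng,
                                roi_masks=roi_masks,
                                record_paths=keep_streamlines,
                                record_visits=True)
    counts = np.bincount(res.visit_voxels,
                         minlength=int(np.prod(grid.shape)))
    counts = counts.reshape(grid.shape).astype(np.int64)
    conn = SeedConnectivity(seed_voxel=seed_voxel, counts=counts,
                            n_streamlines=params.n_streamlines)
    streamlines = None
    if keep_streamlines:
        streamlines = [
            Streamline(points=p, seed_voxel=seed_voxel, reason=str(r))
            for p, r in zip(res.paths, res.reasons)
        ]
    return conn, streamlines, res.roi_hits


def global_profile(seed_profiles) -> np.ndarray:
    """Voxelwise sum of per-seed connectivity volumes for one subject."""
    profiles = list(seed_profiles)
    if not profiles:
        raise ValueError("no seed profiles given")
    arrays = [p.counts if isinstance(p, SeedConnectivity) else np.asarray(p)
              for p in profiles]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ValueError(f"profile grids differ: {a.shape} vs {shape}")
    return np.sum(arrays, axis=0)


def group_average(subject_profiles, grids: list[VolumeGrid] | None = None
                  ) -> np.ndarray:
    """Mean volume across subjects (the group profile in the common space)."""
    vols = [np.asarray(v, dtype=float) for v in subject_profiles]
    if grids is not None:
        for g in grids[1:]:
            check_same_grid(grids[0], g, "subject profiles")
    shape = vols[0].shape
    for v in vols[1:]:
        if v.shape != shape:
            raise ValueError(f"profile grids differ: {v.shape} vs {shape}")
    return np.mean(vols, axis=0)
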