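"""Synthetic volumetric phantoms with known tract geometry and terminations.

A phantom is a brain-like lattice with disjoint white-matter (WM) and
grey-matter (GM) compartments.  Each "tract" is a parametric polyline inside
the WM whose surrounding corridor of voxels carries the curve tangent as its
principal fibre orientation; the curve's cortical end defines a ground-truth
termination patch on the WM surface (the grey–white interface, GWI).  A
multi-subject cohort applies small random displacements ("jitter") to the
curve control points, emulating residual anatomical variability after
registration to a common space.  Binary functional-domain maps are planted in
the GM with a controlled overlap against a chosen tract's termination patch,
standing in for thresholded meta-analytic activation maps.

Randomness enters generation only through the jitter; a spec's ``rng_seed``
therefore fully determines the cohort, and subject ``k`` is reproducible from
``(rng_seed, k)`` alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import VolumeGrid
from .gwi import surface_mask


class PhantomGenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TractGeometry:
    """A tract as a polyline in world mm.

    The *last* control point is the cortical end: it must lie on the WM
    compartment boundary and defines the termination patch.  The first control
    point is the deep end near which the tract-selection ROI is placed.
    """

    name: str
    control_points: np.ndarray  # (k, 3) world mm
    corridor_radius_mm: float = 8.0
    patch_radius_mm: float = 8.0
    roi_arc_fraction: float = 0.1  # where along the curve the tract ROI sits

    def __post_init__(self):
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError(f"tract {self.name!r}: control_points must be (k>=2, 3)")
        object.__setattr__(self, "control_points", pts)


@dataclass(frozen=True)
class DomainSpec:
    """A planted functional-domain map: a GM ball plus a controlled fraction
    of one tract's termination patch."""

    name: str
    centre: tuple[float, float, float]  # world mm
    radius_mm: float
    tract: str | None = None
    target_overlap: float = 0.0  # requested |map ∩ patch| / |patch|


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one cohort.

    Defaults emulate the study conditions: a 40×48×40 lattice of 2 mm
    isotropic voxels, a WM slab whose surface holds ≈3000 GWI voxels,
    24 subjects, 10° angular dispersion of the orientation field and 1 mm
    control-point jitter between subjects.
    """

    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size: float = 2.0
    tracts: tuple[TractGeometry, ...] = ()
    dispersion_deg: float = 10.0
    n_subjects: int = 24
    subject_jitter_mm: float = 1.0
    domains: tuple[DomainSpec, ...] = ()
    rng_seed: int = 0
    wm_half_extent_mm: tuple[float, float, float] = (21.0, 26.0, 21.0)
    gm_thickness_vox: int = 2
    lobe_world_min: tuple[float, float, float] | None = None
    lobe_world_max: tuple[float, float, float] | None = None
    background_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be strictly positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.dispersion_deg < 0 or self.subject_jitter_mm < 0:
            raise ValueError("dispersion and jitter must be non-negative")

    @property
    def n_tracts(self) -> int:
        return len(self.tracts)

    def grid(self) -> VolumeGrid:
        return VolumeGrid(shape=self.grid_shape, voxel_size=self.voxel_size)


@dataclass
class Phantom:
    """One subject's synthetic anatomy and ground truth."""

    grid: VolumeGrid
    wm_mask: np.ndarray
    gm_mask: np.ndarray
    lobe_mask: np.ndarray
    brain_mask: np.ndarray
    orientation_field: np.ndarray  # shape + (3,); unit vectors inside WM
    dispersion_deg: float
    truth_terminations: dict[str, np.ndarray]
    tract_rois: dict[str, np.ndarray]
    domain_maps: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    @property
    def exclusion_mask(self) -> np.ndarray:
        return ~self.wm_mask


# ---------------------------------------------------------------------------
# curve machinery


def _resample_polyline(points: np.ndarray, ds: float):
    """Dense samples and unit tangents along a polyline at spacing ~ds."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len == 0):
        keep = np.concatenate([[True], seg_len > 0])
        points = points[keep]
        seg = np.diff(points, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n = max(int(np.ceil(total / ds)) + 1, 2)
    s = np.linspace(0.0, total, n)
    samples = np.empty((n, 3))
    tangents = np.empty((n, 3))
    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[seg_idx]) / seg_len[seg_idx]
    samples = points[seg_idx] + frac[:, None] * seg[seg_idx]
    tangents = seg[seg_idx] / seg_len[seg_idx, None]
    return samples, tangents, s, total


def _wm_box_bounds(spec: PhantomSpec):
    lo = -np.asarray(spec.wm_half_extent_mm, dtype=float)
    hi = np.asarray(spec.wm_half_extent_mm, dtype=float)
    return lo, hi


# ---------------------------------------------------------------------------
# generation


def generate_phantom(spec: PhantomSpec, subject: int | None = None) -> Phantom:
    """Build one phantom.

    ``subject=None`` builds the jitter-free template (the common space);
    ``subject=k`` applies that subject's control-point jitter, drawn from an
    RNG seeded by ``(spec.rng_seed, k)`` so each subject is reproducible in
    isolation.
    """
    grid = spec.grid()
    lo, hi = _wm_box_bounds(spec)

    gx, gy, gz = grid.world_coordinate_grids()
    centres = np.stack([gx, gy, gz], axis=-1)

    eps = 1e-6  # voxel-centre membership must not fall to rounding
    wm = np.all((centres >= lo - eps) & (centres <= hi + eps), axis=-1)
    struct = ndimage.generate_binary_structure(3, 1)
    gm = ndimage.binary_dilation(wm, structure=struct,
                                 iterations=int(spec.gm_thickness_vox)) & ~wm
    brain = wm | gm

    lobe = np.ones(grid.shape, dtype=bool)
    if spec.lobe_world_min is not None:
        lobe &= np.all(centres >= np.asarray(spec.lobe_world_min, float), axis=-1)
    if spec.lobe_world_max is not None:
        lobe &= np.all(centres <= np.asarray(spec.lobe_world_max, float), axis=-1)

    surf = surface_mask(wm)

    # jitter tract control points for this subject
    tracts = []
    if subject is None:
        for t in spec.tracts:
            pts = t.control_points
            if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
                raise PhantomGenerationError(
                    f"tract {t.name!r}: control points leave the WM compartment")
            tracts.append(t)
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence((int(spec.rng_seed), int(subject))))
        for t in spec.tracts:
            jitter = rng.normal(0.0, spec.subject_jitter_mm,
                                size=t.control_points.shape)
            pts = np.clip(t.control_points + jitter, lo, hi)
            tracts.append(replace(t, control_points=pts))

    wm_idx = np.argwhere(wm)
    wm_centres = grid.voxel_to_world(wm_idx)

    orientation = np.zeros(grid.shape + (3,), dtype=float)
    bg = np.asarray(spec.background_direction, dtype=float)
    bg = bg / np.linalg.norm(bg)
    orientation[wm] = bg

    best_dist = np.full(len(wm_idx), np.inf)
    n_corridors = np.zeros(len(wm_idx), dtype=np.int8)
    truth: dict[str, np.ndarray] = {}
    rois: dict[str, np.ndarray] = {}

    for t in tracts:
        samples, tangents, s, total = _resample_polyline(
            t.control_points, ds=grid.voxel_size / 4.0)
        if not np.all(grid.inside(grid.world_to_voxel(samples))):
            raise PhantomGenerationError(
                f"tract {t.name!r}: curve exits the grid")
        tree = cKDTree(samples)
        dist, nearest = tree.query(wm_centres)
        in_corridor = dist <= t.corridor_radius_mm
        n_corridors[in_corridor] += 1
        take = in_corridor & (dist < best_dist)
        best_dist[take] = dist[take]
        vox = wm_idx[take]
        orientation[vox[:, 0], vox[:, 1], vox[:, 2]] = tangents[nearest[take]]

        # ground-truth termination patch on the WM surface around the cortical end
        end = t.control_points[-1]
        d_end = np.linalg.norm(centres - end, axis=-1)
        truth[t.name] = surf & (d_end <= t.patch_radius_mm)

        # tract-selection ROI: a one-voxel-thick slab through the corridor,
        # perpendicular to the dominant tangent axis near the deep end
        roi_s = t.roi_arc_fraction * total
        roi_i = int(np.argmin(np.abs(s - roi_s)))
        axis = int(np.argmax(np.abs(tangents[roi_i])))
        roi_vox = grid.world_to_voxel(samples[roi_i])
        corridor_mask = np.zeros(grid.shape, dtype=bool)
        cv = wm_idx[in_corridor]
        corridor_mask[cv[:, 0], cv[:, 1], cv[:, 2]] = True
        idx_axis = np.indices(grid.shape)[axis]
        rois[t.name] = corridor_mask & (idx_axis == roi_vox[axis])

    metadata = {
        "subject": subject,
        "rng_seed": int(spec.rng_seed),
        "overlapping_tract_corridors": bool(np.any(n_corridors > 1)),
    }
    phantom = Phantom(
        grid=grid, wm_mask=wm, gm_mask=gm, lobe_mask=lobe, brain_mask=brain,
        orientation_field=orientation, dispersion_deg=spec.dispersion_deg,
        truth_terminations=truth, tract_rois=rois, domain_maps={},
        metadata=metadata,
    )
    for d in spec.domains:
        phantom.domain_maps[d.name] = generate_domain_map(phantom, d)
    return phantom


def generate_cohort(spec: PhantomSpec) -> list[Phantom]:
    """One phantom per subject; jitter 0 makes all subjects identical."""
    return [generate_phantom(spec, subject=k) for k in range(spec.n_subjects)]


def generate_domain_map(phantom: Phantom, dspec: DomainSpec) -> np.ndarray:
    """Plant a binary functional-domain map.

    The map is a ball of grey-matter (plus GWI-surface) voxels around the
    spec's centre, with exactly ``round(target_overlap * |patch|)`` voxels of
    the named tract's termination patch included (those nearest the centre)
    and the rest of that patch excluded, so the achieved overlap proportion is
    within rounding of the request.
    """
    grid = phantom.grid
    centre = np.asarray(dspec.centre, dtype=float)
    if not grid.inside(grid.world_to_voxel(centre)):
        raise ValueError(f"domain {dspec.name!r}: centre outside the grid")
    if not (0.0 <= dspec.target_overlap <= 1.0):
        raise ValueError(
            f"domain {dspec.name!r}: target overlap {dspec.target_overlap} "
            "unreachable; the maximum achievable proportion is 1.0")

    gx, gy, gz = grid.world_coordinate_grids()
    d_centre = np.sqrt((gx - centre[0]) ** 2 + (gy - centre[1]) ** 2
                       + (gz - centre[2]) ** 2)
    surf = surface_mask(phantom.wm_mask)
    support = (phantom.gm_mask | surf) & (d_centre <= dspec.radius_mm)

    all_truth = np.zeros(grid.shape, dtype=bool)
    for m in phantom.truth_terminations.values():
        all_truth |= m

    if dspec.tract is None:
        return support & ~all_truth

    patch = phantom.truth_terminations[dspec.tract]
    n_patch = int(patch.sum())
    k = int(round(dspec.target_overlap * n_patch))
    if n_patch == 0 and dspec.target_overlap > 0:
        raise ValueError(
            f"domain {dspec.name!r}: tract {dspec.tract!r} has an empty "
            "termination patch; the maximum achievable overlap is 0.0")

    domain = support & ~all_truth
    if k > 0:
        pidx = np.argwhere(patch)
        pd = np.linalg.norm(grid.voxel_to_world(pidx) - centre, axis=1)
        flat = np.ravel_multi_index(tuple(pidx.T), grid.shape)
        order = np.lexsort((flat, pd))
        chosen = pidx[order[:k]]
        domain[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True

    achieved = (domain & patch).sum() / max(n_patch, 1)
    if abs(achieved - dspec.target_overlap) > 0.05:
        warnings.warn(
            f"domain {dspec.name!r}: achieved overlap {achieved:.3f} vs "
            f"target {dspec.target_overlap:.3f}", stacklevel=2)
    return domain


# ---------------------------------------------------------------------------
# on-disk form (NIfTI volumes + a JSON manifest)


def save_phantom(phantom: Phantom, out_dir) -> dict:
    """Write a phantom as NIfTI volumes plus a manifest JSON; returns the
    manifest (paths of every per-tract truth file, masks and metadata)."""
    import json
    from pathlib import Path

    from .io import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = phantom.grid
    manifest = {"dispersion_deg": phantom.dispersion_deg,
                "metadata": phantom.metadata, "volumes": {}}
    vols = manifest["volumes"]
    for name, arr in [("wm_mask", phantom.wm_mask), ("gm_mask", phantom.gm_mask),
                      ("lobe_mask", phantom.lobe_mask),
                      ("brain_mask", phantom.brain_mask)]:
        vols[name] = str(write_volume(arr, grid, out / f"{name}.nii.gz"))
    vols["orientation_field"] = str(write_volume(
        phantom.orientation_field, grid, out / "orientation_field.nii.gz"))
    for group, d in [("truth", phantom.truth_terminations),
                     ("tract_roi", phantom.tract_rois),
                     ("domain", phantom.domain_maps)]:
        for name, arr in d.items():
            vols[f"{group}_{name}"] = str(write_volume(
                arr, grid, out / f"{group}_{name}.nii.gz"))
    (out / "phantom.json").write_text(json.dumps(manifest, indent=2,
                                                 sort_keys=True))
    return manifest


def load_phantom(in_dir) -> Phantom:
    """Load a phantom previously written by :func:`save_phantom`."""
    import json
    from pathlib import Path

    from .io import read_volume

    src = Path(in_dir)
    manifest = json.loads((src / "phantom.json").read_text())
    vols = manifest["volumes"]
    wm, grid = read_volume(vols["wm_mask"])
    masks = {}
    for key in ("gm_mask", "lobe_mask", "brain_mask"):
        arr, _ = read_volume(vols[key], reference=grid)
        masks[key] = arr.astype(bool)
    orient, _ = read_volume(vols["orientation_field"], reference=grid)
    groups: dict[str, dict[str, np.ndarray]] = {
        "truth": {}, "tract_roi": {}, "domain": {}}
    for key, path in vols.items():
        for prefix in groups:
            if key.startswith(prefix + "_"):
                arr, _ = read_volume(path, reference=grid)
                groups[prefix][key[len(prefix) + 1:]] = arr.astype(bool)
    return Phantom(
        grid=grid, wm_mask=wm.astype(bool), gm_mask=masks["gm_mask"],
        lobe_mask=masks["lobe_mask"], brain_mask=masks["brain_mask"],
        orientation_field=np.asarray(orient, dtype=float),
        dispersion_deg=float(manifest["dispersion_deg"]),
        truth_terminations=groups["truth"], tract_rois=groups["tract_roi"],
        domain_maps=groups["domain"], metadata=manifest["metadata"])


# ---------------------------------------------------------------------------
# canonical geometries


def default_tract_geometries(corridor_radius_mm: float = 8.0,
                             patch_radius_mm: float = 8.0):
    """Three parallel tracts ending on the superior WM face at well-separated
    patches, with deep ends at z = -16 mm."""
    ends = {"alpha": (-10.0, -14.0), "beta": (10.0, -6.0), "gamma": (-2.0, 14.0)}
    geoms = []
    for name, (cx, cy) in ends.items():
        pts = np.array([[cx, cy, -16.0], [cx, cy, 21.0]])
        geoms.append(TractGeometry(name=name, control_points=pts,
                                   corridor_radius_mm=corridor_radius_mm,
                                   patch_radius_mm=patch_radius_mm))
    return tuple(geoms)


def default_domain_specs():
    """Two planted domains: one matched to tract alpha and one to beta, each
    covering 70% of its tract's termination patch; tract gamma gets none."""
    return (
        DomainSpec(name="memory", centre=(-10.0, -14.0, 25.0), radius_mm=7.0,
                   tract="alpha", target_overlap=0.7),
        DomainSpec(name="vision", centre=(10.0, -6.0, 25.0), radius_mm=7.0,
                   tract="beta", target_overlap=0.7),
    )


def three_tract_cohort_spec(n_subjects: int = 12, rng_seed: int = 0,
                            dispersion_deg: float = 10.0,
                            subject_jitter_mm: float = 1.0) -> PhantomSpec:
    """Cohort used for end-to-end analysis runs: three planted tracts, two
    planted domains, seeds restricted to the superior cortical region (the
    'lobe' under study)."""
    return PhantomSpec(
        tracts=default_tract_geometries(),
        domains=default_domain_specs(),
        n_subjects=n_subjects,
        rng_seed=rng_seed,
        dispersion_deg=dispersion_deg,
        subject_jitter_mm=subject_jitter_mm,
        lobe_world_min=(-1e9, -1e9, 19.0),
    )
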