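"""Pairwise-evidence statistics on termination maps.

For every ordered tract pair (A, B) a paired one-sided test asks, voxel by
voxel, whether A's termination probability exceeds B's across subjects.  The
test statistic is the one-sample t on the paired differences; family-wise
error over the analysis mask is controlled with the permutation
maximum-statistic method, the null being generated by random sign-flips of
whole subject difference maps (all 2^n sign patterns are enumerated
exhaustively whenever that is no more work than sampling).  Significance
additionally carries a Bonferroni factor across the pairwise tests.

Summing a tract's T-1 binary win maps yields its evidence map on the scale
0..T-1 (with seven tracts: 0 = greater than no other tract, 6 = greater than
all).  The termination ROI of a tract keeps the voxels at the two highest
evidence values; an all-zero map yields an empty ROI (some tracts never reach
the required level of evidence).  An ROI can be subdivided into anterior
superior / anterior inferior / posterior sections at a coronal plane plus a
superior boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid


@dataclass
class PairwiseResult:
    """Outcome of one ordered pairwise comparison A > B."""

    tract_a: str
    tract_b: str
    significant: np.ndarray      # binary volume (within mask)
    p_fwe: np.ndarray            # per-voxel FWE p-values (1 outside mask)
    t_observed: np.ndarray       # observed statistic volume (0 outside mask)
    n_permutations: int
    exhaustive: bool
    alpha: float
    m_bonferroni: int


def _t_statistics(signs: np.ndarray, diffs: np.ndarray,
                  sum_sq: np.ndarray) -> np.ndarray:
    """Voxelwise paired t for a block of sign patterns.

    ``signs`` is (p, n), ``diffs`` (n, v).  Sign-flipping leaves each d_s^2
    unchanged, so the sample variance follows from the flipped mean and the
    fixed per-voxel sum of squares.
    """
    n = diffs.shape[0]
    mean = signs @ diffs / n
    var = (sum_sq[None, :] - n * mean ** 2) / (n - 1)
    np.clip(var, 0.0, None, out=var)
    se = np.sqrt(var / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, 0.0)
    return t


def paired_permutation_map(maps_a, maps_b, mask: np.ndarray,
                           alpha: float = 0.05,
                           n_permutations: int = 5000,
                           m_bonferroni: int = 42,
                           rng: np.random.Generator | None = None,
                           tract_a: str = "A", tract_b: str = "B",
                           block: int = 1024) -> PairwiseResult:
    """Sign-flip max-statistic FWE comparison of two paired map sets.

    ``maps_a`` and ``maps_b`` are paired by subject (same order, length >= 2)
    and must be the *un-rescaled* termination maps.  A voxel is significant
    when its FWE p-value is below ``alpha / m_bonferroni``.
    """
    a = np.asarray([np.asarray(m, dtype=float) for m in maps_a])
    b = np.asarray([np.asarray(m, dtype=float) for m in maps_b])
    if a.shape != b.shape:
        raise ValueError(f"paired map stacks differ: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 subjects for the paired test, got {n}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape[1:]:
        raise ValueError("mask grid does not match the maps")

    diffs = (a - b)[:, mask]                      # (n, v)
    sum_sq = np.sum(diffs ** 2, axis=0)
    t_obs = _t_statistics(np.ones((1, n)), diffs, sum_sq)[0]

    exhaustive = 2 ** n <= n_permutations
    if exhaustive:
        n_perm = 2 ** n
        bits = np.arange(n_perm)
        signs_all = np.where((bits[:, None] >> np.arange(n)) & 1, 1.0, -1.0)
    else:
        if rng is None:
            rng = np.random.default_rng()
        n_perm = n_permutations
        signs_all = None

    exceed = np.zeros(t_obs.shape, dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        if exhaustive:
            signs = signs_all[done:done + m]
        else:
            signs = np.where(rng.random((m, n)) < 0.5, 1.0, -1.0)
        t_perm = _t_statistics(signs, diffs, sum_sq)
        max_stat = t_perm.max(axis=1) if t_perm.shape[1] else np.zeros(m)
        exceed += (max_stat[:, None] >= t_obs[None, :]).sum(axis=0)
        done += m

    if exhaustive:
        p = exceed / n_perm
    else:
        p = (1 + exceed) / (n_perm + 1)

    p_vol = np.ones(mask.shape, dtype=float)
    p_vol[mask] = p
    t_vol = np.zeros(mask.shape, dtype=float)
    t_vol[mask] = t_obs
    sig = np.zeros(mask.shape, dtype=bool)
    sig[mask] = p < alpha / m_bonferroni
    return PairwiseResult(
        tract_a=tract_a, tract_b=tract_b, significant=sig, p_fwe=p_vol,
        t_observed=t_vol, n_permutations=n_perm, exhaustive=exhaustive,
        alpha=alpha, m_bonferroni=m_bonferroni)


@dataclass
class EvidenceMap:
    """Per-voxel count of won pairwise comparisons, scale 0..T-1."""

    tract: str
    values: np.ndarray
    n_tracts: int


def evidence_map(tract: str, pairwise_results: list[PairwiseResult],
                 n_tracts: int) -> EvidenceMap:
    """Sum a tract's T-1 binary win maps into its evidence map."""
    mine = [r for r in pairwise_results if r.tract_a == tract]
    if len(mine) != n_tracts - 1:
        raise ValueError(
            f"tract {tract!r}: expected {n_tracts - 1} pairwise results with "
            f"it as A, got {len(mine)}")
    values = np.sum([r.significant.astype(np.int64) for r in mine], axis=0)
    return EvidenceMap(tract=tract, values=values, n_tracts=n_tracts)


@dataclass
class EvidenceROI:
    """Termination ROI extracted from an evidence map."""

    tract: str
    mask: np.ndarray
    rule: str
    subdivisions: dict[str, np.ndarray] | None = None

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


def evidence_roi(evidence: EvidenceMap, rule: str = "two_highest") -> EvidenceROI:
    """Threshold an evidence map at its greatest levels of evidence.

    ``two_highest`` keeps voxels at the two highest scale values (T-2 and
    T-1, i.e. above the greater-than-half display threshold); ``max`` keeps
    only voxels greater than all other tracts (value T-1).  The result may be
    empty when no voxel reaches the required level of evidence.
    """
    top = evidence.n_tracts - 1
    if rule == "two_highest":
        mask = evidence.values >= top - 1
    elif rule == "max":
        mask = evidence.values >= top
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return EvidenceROI(tract=evidence.tract, mask=np.asarray(mask, bool),
                       rule=rule)


def subdivide_roi(roi: EvidenceROI, grid: VolumeGrid,
                  y_plane_mm: float = -27.0,
                  superior_boundary: float | np.ndarray = 0.0
                  ) -> dict[str, np.ndarray]:
    """Split an ROI into posterior / anterior-superior / anterior-inferior.

    Voxels with world y < ``y_plane_mm`` are posterior; the remaining
    anterior voxels are split by ``superior_boundary`` — either a world-mm
    z-plane (superior means z >= plane) or an explicit binary mask of the
    superior territory.  The three masks partition the ROI.
    """
    if roi.empty:
        raise ValueError(f"ROI {roi.tract!r} is empty; nothing to subdivide")
    _, wy, wz = grid.world_coordinate_grids()
    posterior = roi.mask & (wy < y_plane_mm)
    anterior = roi.mask & ~posterior
    if isinstance(superior_boundary, np.ndarray):
        sup = anterior & superior_boundary.astype(bool)
    else:
        sup = anterior & (wz >= float(superior_boundary))
    inf = anterior & ~sup
    parts = {"ant_sup": sup, "ant_inf": inf, "post": posterior}
    for name, m in parts.items():
        if not m.any():
            warnings.warn(f"ROI section {name!r} is empty", stacklevel=2)
    roi.subdivisions = parts
    return parts
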