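"""Termination-ROI × functional-domain overlap with a permutation null.

The overlap of a termination ROI A with a domain map B is the proportion
P = |A ∩ B| / |A|.  Chance overlap is calibrated by re-drawing B many times
as a uniform random arrangement of grey-matter voxels of the same size and
recomputing P; the observed overlap is reported only when it exceeds the
(1 - alpha/m) quantile of that null (the Bonferroni-corrected 95% gate).
Assembling every ROI (or ROI subdivision) against every domain map yields the
overlap matrix, whose cells carry P only where the gate passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VolumeGrid


@dataclass
class OverlapTest:
    """One ROI × domain overlap with its permutation null."""

    tract: str
    domain: str
    hemisphere: str
    proportion: float
    n_a: int
    n_b: int
    n_ab: int
    null: np.ndarray
    threshold: float
    quantile_level: float
    significant: bool


@dataclass
class OverlapMatrix:
    """Overlap proportions, reported only where significant (NaN otherwise)."""

    table: pd.DataFrame
    tests: list[OverlapTest] = field(default_factory=list)
    alpha: float = 0.05
    m_tests: int = 1

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="")

    def to_records(self) -> list[dict]:
        return [
            {
                "tract": t.tract, "domain": t.domain, "hemisphere": t.hemisphere,
                "proportion": t.proportion, "n_a": t.n_a, "n_b": t.n_b,
                "n_ab": t.n_ab, "threshold": t.threshold,
                "significant": t.significant,
            }
            for t in self.tests
        ]


def overlap_proportion(a_mask: np.ndarray, b_mask: np.ndarray):
    """Exact overlap proportion |A ∩ B| / |A| with its integer counts."""
    a = np.asarray(a_mask, dtype=bool)
    b = np.asarray(b_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("overlap proportion undefined for an empty ROI")
    n_ab = int((a & b).sum())
    return n_ab / n_a, n_a, int(b.sum()), n_ab


def permutation_null(a_mask: np.ndarray, size_b: int, gm_mask: np.ndarray,
                     n_permutations: int = 10_000,
                     rng: np.random.Generator | None = None,
                     _chunk_budget: int = 5_000_000) -> np.ndarray:
    """Null overlap proportions against random same-size grey-matter maps.

    Each draw places ``size_b`` voxels uniformly at random without replacement
    within the grey-matter mask and records |A ∩ draw| / |A|.
    """
    a = np.asarray(a_mask, dtype=bool)
    gm = np.asarray(gm_mask, dtype=bool)
    if a.shape != gm.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {gm.shape}")
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("overlap proportion undefined for an empty ROI")
    n_gm = int(gm.sum())
    if size_b > n_gm:
        raise ValueError(
            f"cannot place {size_b} voxels in a grey-matter mask of {n_gm}")
    if rng is None:
        rng = np.random.default_rng()
    if size_b == 0:
        return np.zeros(n_permutations)

    a_in_gm = a[gm]  # indicator of A over the gm voxel list
    null = np.empty(n_permutations)
    chunk = max(1, _chunk_budget // max(n_gm, 1))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        r = rng.random((m, n_gm))
        sel = np.argpartition(r, size_b - 1, axis=1)[:, :size_b]
        null[done:done + m] = a_in_gm[sel].sum(axis=1) / n_a
        done += m
    return null


def overlap_test(a_mask: np.ndarray, b_mask: np.ndarray, gm_mask: np.ndarray,
                 alpha: float = 0.05, m_tests: int = 1,
                 n_permutations: int = 10_000,
                 rng: np.random.Generator | None = None,
                 tract: str = "A", domain: str = "B",
                 hemisphere: str = "both") -> OverlapTest:
    """Overlap proportion with the Bonferroni-corrected permutation gate.

    Significant iff the observed P strictly exceeds the empirical
    (1 - alpha/m_tests) quantile (higher order statistic) of the null sample.
    """
    p_obs, n_a, n_b, n_ab = overlap_proportion(a_mask, b_mask)
    null = permutation_null(a_mask, n_b, gm_mask,
                            n_permutations=n_permutations, rng=rng)
    level = 1.0 - alpha / m_tests
    threshold = float(np.quantile(null, level, method="higher"))
    return OverlapTest(
        tract=tract, domain=domain, hemisphere=hemisphere,
        proportion=p_obs, n_a=n_a, n_b=n_b, n_ab=n_ab, null=null,
        threshold=threshold, quantile_level=level,
        significant=bool(p_obs > threshold))


def split_hemispheres(mask: np.ndarray, grid: VolumeGrid):
    """Left/right split at the world x = 0 plane (x < 0 is left)."""
    wx, _, _ = grid.world_coordinate_grids()
    m = np.asarray(mask, dtype=bool)
    return {"L": m & (wx < 0), "R": m & (wx >= 0)}


def overlap_matrix(rois: dict[str, np.ndarray],
                   domain_maps: dict[str, np.ndarray],
                   gm_mask: np.ndarray, grid: VolumeGrid,
                   alpha: float = 0.05, n_permutations: int = 10_000,
                   m_tests: int | None = None,
                   hemisphere_split: bool = False,
                   rng: np.random.Generator | None = None) -> OverlapMatrix:
    """One overlap test per (ROI or subdivision) × domain (× hemisphere).

    Empty ROIs (tracts whose evidence never reached the required level) are
    skipped with a warning.  ``m_tests`` defaults to the number of tests
    actually performed.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows: list[tuple[str, str, np.ndarray]] = []
    for name, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        parts = split_hemispheres(mask, grid) if hemisphere_split \
            else {"both": mask}
        for hemi, part in parts.items():
            if not part.any():
                warnings.warn(
                    f"ROI {name!r} ({hemi}) is empty: row skipped", stacklevel=2)
                continue
            rows.append((name, hemi, part))
    m = m_tests if m_tests is not None else max(len(rows) * len(domain_maps), 1)

    tests: list[OverlapTest] = []
    index = pd.MultiIndex.from_tuples([(n, h) for n, h, _ in rows],
                                      names=["tract", "hemisphere"])
    table = pd.DataFrame(np.nan, index=index, columns=list(domain_maps))
    for name, hemi, a in rows:
        for dom, b in domain_maps.items():
            t = overlap_test(a, b, gm_mask, alpha=alpha, m_tests=m,
                             n_permutations=n_permutations, rng=rng,
                             tract=name, domain=dom, hemisphere=hemi)
            tests.append(t)
            if t.significant:
                table.loc[(name, hemi), dom] = t.proportion
    return OverlapMatrix(table=table, tests=tests, alpha=alpha, m_tests=m)
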