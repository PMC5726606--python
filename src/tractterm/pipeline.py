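"""End-to-end orchestration: phantom → GWI → tracking → termination maps →
evidence maps → overlap matrix, with every output written to disk and listed
in a manifest.  Re-running with the same config reproduces every file."""

from __future__ import annotations

import json
import logging
from itertools import permutations
from pathlib import Path

import numpy as np

from . import evidence as ev
from . import overlap as ov
from . import termmap as tm
from .config import PipelineConfig
from .gwi import build_exclusion_mask, extract_gwi, surface_mask
from .io import write_seeds_tsv, write_volume
from .phantom import generate_cohort, generate_phantom, three_tract_cohort_spec
from .tracking import group_average

log = logging.getLogger("tractterm")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis on a planted three-tract cohort.

    Returns the manifest dict (also written to ``<out_dir>/manifest.json``)
    recording every output path, all parameters and the RNG seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "outputs": {}}
    paths = manifest["outputs"]

    spec = three_tract_cohort_spec(
        n_subjects=config.phantom.n_subjects,
        rng_seed=config.rng_seed,
        dispersion_deg=config.phantom.dispersion_deg,
        subject_jitter_mm=config.phantom.subject_jitter_mm,
    )
    log.info("phantom: generating template and %d subjects", spec.n_subjects)
    template = generate_phantom(spec)
    cohort = generate_cohort(spec)
    grid = template.grid
    tract_names = [t.name for t in spec.tracts]
    n_tracts = len(tract_names)

    paths["wm_mask"] = str(write_volume(template.wm_mask, grid, out / "wm_mask.nii.gz"))
    paths["gm_mask"] = str(write_volume(template.gm_mask, grid, out / "gm_mask.nii.gz"))
    paths["lobe_mask"] = str(write_volume(template.lobe_mask, grid,
                                          out / "lobe_mask.nii.gz"))
    paths["exclusion_mask"] = str(write_volume(
        build_exclusion_mask(template.wm_mask), grid, out / "exclusion_mask.nii.gz"))
    for name, mask in template.truth_terminations.items():
        paths[f"truth_{name}"] = str(write_volume(
            mask, grid, out / f"truth_{name}.nii.gz"))
    for name, mask in template.domain_maps.items():
        paths[f"domain_{name}"] = str(write_volume(
            mask, grid, out / f"domain_{name}.nii.gz"))

    log.info("gwi: extracting seeds")
    seeds = extract_gwi(template.wm_mask, template.lobe_mask)
    manifest["n_seeds"] = seeds.count
    paths["seeds"] = str(write_seeds_tsv(seeds.indices, out / "seeds.tsv"))

    rois = [tm.TractROI(name=n, mask=template.tract_rois[n]) for n in tract_names]
    for r in rois:
        paths[f"tract_roi_{r.name}"] = str(write_volume(
            r.mask, grid, out / f"tract_roi_{r.name}.nii.gz"))

    log.info("tracking + termination maps: %d subjects x %d seeds x %d streamlines",
             len(cohort), seeds.count, config.tracking.n_streamlines)
    raw_subject: dict[str, list[np.ndarray]] = {n: [] for n in tract_names}
    smoothed: dict[str, list[np.ndarray]] = {n: [] for n in tract_names}
    global_profiles = []
    for k, subject in enumerate(cohort):
        gcounts = grid.zeros(dtype=np.int64) if config.write_global_profile else None
        maps = tm.subject_termination_maps(
            subject, seeds, rois, config.tracking, subject=k,
            global_counts=gcounts)
        for name, m in maps.items():
            raw_subject[name].append(m.proportions)
            smoothed[name].append(
                tm.smooth_map(m.proportions, grid, config.stats.fwhm_mm))
            paths[f"{name}_{k:02d}"] = str(write_volume(
                m.proportions, grid, out / f"{name}_{k:02d}.nii.gz"))
        if gcounts is not None:
            global_profiles.append(gcounts)
    if global_profiles:
        paths["global_profile_group"] = str(write_volume(
            group_average(global_profiles), grid,
            out / "global_profile_group.nii.gz"))

    log.info("termmap: group maps")
    for name in tract_names:
        group = tm.group_map(smoothed[name])
        paths[f"{name}_group_raw"] = str(write_volume(
            tm.rescale_unit(group), grid, out / f"{name}_group_raw.nii.gz"))

    log.info("evidence: pairwise permutation maps")
    analysis_mask = seeds.as_mask(grid)
    m_bonf = config.stats.m_bonferroni or n_tracts * (n_tracts - 1)
    perm_rng = np.random.default_rng(
        np.random.SeedSequence((config.rng_seed, 101)))
    results = []
    # statistics run on the un-rescaled, unsmoothed subject maps
    for a, b in permutations(tract_names, 2):
        res = ev.paired_permutation_map(
            raw_subject[a], raw_subject[b], analysis_mask,
            alpha=config.stats.alpha,
            n_permutations=config.stats.n_permutations_pairwise,
            m_bonferroni=m_bonf, rng=perm_rng, tract_a=a, tract_b=b)
        results.append(res)

    roi_masks = {}
    for name in tract_names:
        emap = ev.evidence_map(name, results, n_tracts)
        paths[f"evidence_{name}"] = str(write_volume(
            emap.values.astype(np.int16), grid, out / f"evidence_{name}.nii.gz"))
        roi = ev.evidence_roi(emap, rule=config.stats.evidence_rule)
        if roi.empty:
            log.warning("evidence ROI for %s is empty", name)
        else:
            roi_masks[name] = roi.mask
            paths[f"evidence_roi_{name}"] = str(write_volume(
                roi.mask, grid, out / f"evidence_roi_{name}.nii.gz"))

    log.info("overlap: %d ROIs x %d domains", len(roi_masks),
             len(template.domain_maps))
    gm_null = template.gm_mask | surface_mask(template.wm_mask)
    ov_rng = np.random.default_rng(
        np.random.SeedSequence((config.rng_seed, 202)))
    matrix = ov.overlap_matrix(
        roi_masks, template.domain_maps, gm_null, grid,
        alpha=config.stats.alpha,
        n_permutations=config.stats.n_permutations_overlap,
        m_tests=config.stats.m_overlap,
        hemisphere_split=config.hemisphere_split, rng=ov_rng)
    matrix.to_tsv(out / "overlap_matrix.tsv")
    paths["overlap_matrix"] = str(out / "overlap_matrix.tsv")
    detail_path = out / "overlap_tests.json"
    detail_path.write_text(json.dumps(
        {"rng_seed": config.rng_seed, "m_tests": matrix.m_tests,
         "tests": matrix.to_records()}, indent=2))
    paths["overlap_tests"] = str(detail_path)

    manifest["rng_seed"] = config.rng_seed
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
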