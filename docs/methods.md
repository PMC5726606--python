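# Methods

`tractterm` reimplements a cortical *tract-termination mapping* pipeline as a
tested library, and ships a synthetic phantom generator so every stage can be
validated against known ground truth without access to diffusion-MRI data.

## The analysis

The scientific question is *where on the cortex a white-matter tract begins or
ends*, rather than where its body runs. The pipeline answers it in five
stages.

**1. Seeds: the grey–white interface (GWI).** Given a binary white-matter
mask, the seed set is the layer of WM voxels on its external surface — voxels
with at least one face-adjacent (6-neighbourhood) voxel outside the mask —
intersected with a lobe mask restricting the analysis to the cortical region
under study. Everything outside the WM is the tracking *exclusion mask*. The
6-neighbourhood is the conservative, standard surface definition on a voxel
lattice; 26-connectivity is available as an option.

**2. Probabilistic tracking.** From each seed-voxel centre, `n_streamlines`
(protocol default 10,000) streamlines are propagated in 0.5 mm steps. At each
step a direction is drawn from the current voxel's orientation distribution
and sign-aligned with the previous step (the first step explores both signs
of the fibre axis with equal probability). A streamline stops when it enters
the exclusion mask — the stopping point is retained, because terminations on
grey matter are exactly the quantity of interest — when its path length would
exceed 500 mm, or when its direction change over one voxel-length of arc
exceeds the curvature limit (at the default 180° this only forbids exact
reversals). No distance correction is applied. Orientation lookup is
nearest-voxel; with 0.5 mm steps and 2 mm voxels no voxel along the path can
be skipped, so point membership is sufficient for visitation counting, and a
streamline increments a voxel's count at most once. Per-seed counts sum into a
subject's global connectivity profile.

**3. Raw termination maps.** For each tract a one-voxel-thick ROI placed in
the tract body selects its streamlines. A seed's termination-map value is the
proportion of its streamlines intersecting that ROI (1000 of 10,000 → 0.1,
integer-exact). Subject maps are smoothed with a 5 mm-FWHM Gaussian (to
absorb residual anatomical misalignment), averaged across the cohort, and
rescaled to [0, 1] so the map maximum marks the most probable termination
site. Smoothing uses zero boundary handling without mask renormalisation.

**4. Statistical (pairwise-evidence) maps.** For every ordered tract pair
(A, B) a paired one-sided test asks voxelwise whether A's termination
probability exceeds B's across subjects: the statistic is the one-sample t on
paired differences; the family-wise error over the analysis mask (the lobe
GWI) is controlled by the permutation maximum-statistic method with random
sign-flips of whole subject difference maps, with an additional Bonferroni
factor across the pairwise tests (default `T·(T−1)` ordered pairs —
configurable, since the family could equally be counted per tract or per
hemisphere). All `2^n` sign patterns are enumerated exhaustively whenever
that is no more work than sampling (always, for cohorts up to ~12 at the
default 5,000 permutations), making the p-values exact and deterministic.
Zero-variance voxels get statistic 0 and can never be significant. Summing a
tract's T−1 binary win maps yields its *evidence map* on the 0..T−1 scale;
the termination ROI keeps the voxels at the two highest evidence values (or
only the maximum, for the stricter secondary rule), and may legitimately be
empty when no voxel reaches the required level of evidence. ROIs can be
subdivided into posterior / anterior-superior / anterior-inferior sections at
a coronal (y) plane plus a superior boundary given as a z-plane or mask.

*Which maps enter the test.* The pairwise statistics consume the
**un-rescaled, unsmoothed** subject maps. Rescaling is clearly display-only;
smoothing is treated the same way here, for a substantive reason: on
low-noise data the smoothed maps carry deterministic Gaussian-kernel tails
with near-zero between-subject variance, so a paired t marks the entire
kernel support around every true termination significant, inflating every
evidence ROI by the kernel radius (~8.5 mm at 5 mm FWHM with the default
truncation) regardless of effect size. Testing the unsmoothed proportions
keeps the evidence maps anchored to voxels with actual streamline support.

**5. Functional overlap.** The overlap of a termination ROI A with a binary
functional-domain map B is P = |A∩B| / |A|, reported with its integer counts.
Chance overlap is calibrated by re-drawing B 10,000 times as a uniform random
arrangement of grey-matter voxels of the same size; an overlap is reported
only when P strictly exceeds the empirical (1 − α/m) quantile (higher order
statistic) of that null, with m defaulting to the number of matrix cells
tested. For a uniform draw the null overlap count is exactly hypergeometric,
which the tests exploit as a closed form: E[P] = |B|/|GM| when A ⊆ GM. The
uniform null ignores the spatial smoothness of real activation maps and is
therefore anticonservative relative to a smooth-map null; masks can be split
into hemispheres at the world x = 0 plane and tested separately.

## The phantom

The generator emulates, in one common space (no registration is modelled):

- a WM slab with a GM shell (2 voxels thick) on a 40×48×40 lattice of 2 mm
  isotropic voxels; the slab surface carries ≈3000 GWI voxels, matching
  realistic per-lobe seed counts;
- K tracts as polyline curves inside the WM; voxels within a corridor radius
  (default 8 mm) of a curve carry its local tangent as principal orientation,
  other WM voxels a fixed background direction; each curve's cortical end
  defines a ground-truth termination patch (surface voxels within the patch
  radius, default 8 mm) and a one-voxel-thick selection ROI crosses the
  corridor near the deep end;
- per-voxel orientation uncertainty as a single dispersion parameter: a
  sampled direction is the tangent deflected by a half-normal angle
  (SD = dispersion, default 10°) about a uniformly random axis perpendicular
  to it, so the angular deviation is exactly half-normal;
- inter-subject variability as Gaussian jitter (SD default 1 mm) applied to
  curve control points per subject, clipped to the WM compartment —
  emulating residual misalignment after normalisation to a common space;
- functional-domain maps as GM balls planted to cover a controlled fraction
  of a chosen tract's termination patch (the planted 70% stands in for
  strongly associated meta-analytic maps).

Randomness enters generation only through the jitter; `rng_seed` fully
determines a cohort, subject *k* is reproducible from `(rng_seed, k)` alone,
and each seed voxel's streamlines from `(rng_seed, subject, seed)` — any
single streamline can be regenerated in isolation.

What the phantom does **not** model: diffusion signal, fibre crossings,
registration error beyond rigid jitter, spatially structured cortical noise,
and gyral geometry (the "superior temporal" boundary for ROI subdivision is
therefore an explicit plane/mask input rather than an anatomical criterion).
Passing tests demonstrate that the pipeline machinery recovers known
geometry under these idealised conditions; they do not certify performance
on real diffusion data, where false positives/negatives of tractography
dominate.

## Numerical and design choices

- **Voxel membership** is nearest-voxel: voxel *i* owns `[i−0.5, i+0.5)` in
  voxel units; all world planes (e.g. the y = −27 mm subdivision plane) are
  world-space mm under a RAS affine with 0-based indices.
- **Exhaustive vs sampled permutations**: exhaustive enumeration triggers
  when `2^n ≤ n_permutations`; sampled p-values use the (1+b)/(m+1)
  estimator, exhaustive ones the exact fraction.  Note the attainability
  floor: the smallest exhaustive p is `1/2^n`, so with a Bonferroni factor m
  no voxel can ever be significant unless `2^n > m/α` — at α = 0.05 and
  m = 6 that requires at least 7 subjects; cohorts below the floor yield
  empty evidence ROIs by construction, not by error.
- **Overlap gate discreteness**: with a discrete null the strict-exceedance
  rule is slightly conservative; the calibration test computes the expected
  rejection rate in closed form from hypergeometric order statistics rather
  than assuming exactly α.
- **Degenerate inputs**: empty WM masks warn and yield empty seed sets;
  constant maps rescale to all zeros with a warning; empty evidence ROIs are
  skipped (with a warning) in the overlap matrix; an empty ROI makes the
  overlap proportion undefined and raises.
- **Problem sizes in the shipped checks**: the recovery analysis uses 12
  subjects, 3 tracts, and 1,000 streamlines per seed — a deliberate
  scale-down of the full protocol (24 subjects, 7 tracts, 10,000
  streamlines) that keeps every statistical mechanism intact (the sign-flip
  null is exhaustive at n = 12) while the whole analysis runs on a laptop in
  minutes. Calibration uses 500–1,000 repeats of a 2,000-voxel GM universe.

## Known limitations

- Nearest-voxel orientation lookup (no PDF interpolation between voxels).
- The uniform random-voxel overlap null is anticonservative for spatially
  smooth functional maps; a contiguous-blob null is a planned option.
- Tract ROIs are one voxel thick and plane-aligned, as in the protocol;
  oblique tracts crossing a plane obliquely may need manually supplied ROIs.
- The MNI centroid table shipped for real-data ROI placement is provenance
  only; phantoms carry their own ROIs.
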