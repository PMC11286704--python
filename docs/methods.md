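# Methods

## The measurement problem

An MR pancreatic function test acquires a coronal T2-weighted stack before and
~15 minutes after secretin, with matched acquisition parameters (here assumed
matched by protocol: the pipeline validates identical shape and spacing and
performs no registration). Bowel fluid is strongly T2-bright; the secretory
response ΔV = V_post − V_pre in mL is the readout. The pipeline segments
candidate fluid in both stacks jointly, removes predictable non-bowel bright
structures, and integrates volumes from acquisition geometry.

Axis convention everywhere: arrays are indexed `(slice, row, col)`; for
coronal stacks the slice axis is anterior→posterior, rows are
superior→inferior (craniocaudal), columns right→left. A config switch in
`objects` (`craniocaudal_axis`) accommodates other orientations.

## Normalization and thresholding

Pre and post volumes are pooled; the 99.999th percentile (linear
interpolation) of the pooled intensities is the clip value, every voxel is
divided by it and clamped to [0, 1]. Pooling yields a single clip value and a
single threshold that are meaningful for both series, which is what makes
post−pre differences of thresholded volumes coherent. (Per-series clipping
would be a defensible alternative; it breaks that coherence and was not
used.)

The threshold maximizes Kapur's maximum-entropy criterion on a 256-bin pooled
histogram: for a cut t, with bin probabilities p_i and class masses
P₀ = Σ_{i<t} p_i, P₁ = 1 − P₀, the criterion is H₀ + H₁ where
H_c = −Σ (p_i/P_c) ln(p_i/P_c) over the class's nonempty bins. Cuts leaving
an empty class are invalid; ties resolve to the lowest cut (tolerance 1e-10
absorbs float noise between algebraically equal cuts — the implementation is
cumulative-sum based and is tested against a literal exhaustive scan).
Thresholding is strict (`> t`) on the floating-point normalized data.
"Inter-class entropy" is read as Kapur's criterion (sum of within-class
Shannon entropies), the standard entropy-based thresholding objective; Otsu's
between-class *variance* criterion is a different quantity and is not used.

A property worth knowing: on a histogram dominated by one tissue mode with
Gaussian spread, the Kapur cut settles ~2–3σ above that mode, so of the order
of 0.1–1% of tissue voxels exceed the threshold. Scattered speckle is exactly
what the <1 mL cluster filter removes; speckle *attached* to structures adds a
thin surface film (sub-percent volume effect at realistic noise).

## Cluster filtering and morphometry

Clusters are 26-connected 3D components (fluid structures are thin and
oblique; stricter connectivity fragments tubes). Clusters below 1 mL —
measured in native spacing — are removed; the comparison is strict, so an
exactly-1 mL cluster survives.

For classification, the label map is resampled (nearest-neighbor) to cubic
voxels with edge = min in-plane spacing, and per cluster the following are
computed:

- volume (mL), normalized centroid (fractions of field of view),
  axis-aligned bounding-box extents (mm);
- sphericity π^(1/3)(6V)^(2/3)/A with surface area A by exposed-voxel-face
  counting. Face counting is exact and deterministic (a single voxel has
  A = 6 faces, sphericity ≈ 0.806) but overestimates smooth areas by ~1.5×,
  so the scale tops out at the cube's 0.806 and a digital ball measures
  ≈ 0.65. All rule thresholds below are calibrated to this scale;
- principal-axis angle: angle between the leading eigenvector of the voxel
  coordinate covariance and the craniocaudal axis, in [0°, 90°]; clusters
  under 4 voxels are flagged unstable and given angle 0;
- craniocaudal span as a fraction of the field of view.

Removal decisions are mapped back through the shared label map and applied to
the **native** mask, so reported volumes always come from acquisition
geometry.

## Heuristic rule table

The six confounder classes and the feature vocabulary are fixed; the numeric
intervals are an implementation choice (no published ranges exist), tuned on
the synthetic phantoms and shipped as an editable JSON config
(`objects.save_rules` / `load_rules`). First matching rule wins; rule order
is part of the table. Defaults (coordinates as fractions: z
anterior→posterior, y superior→inferior, x right→left):

| class | key intervals |
|---|---|
| bladder | V ≥ 25 mL, sphericity ≥ 0.45, y ≥ 0.65, x ∈ [0.30, 0.70] |
| gallbladder | V ∈ [4, 80] mL, sphericity ≥ 0.50, y ≤ 0.45, x ≤ 0.42 |
| fat rim | sphericity ≤ 0.30, bbox_y ≥ 85 mm, bbox_x ≥ 85 mm |
| spinal canal | span ≥ 0.55, sphericity ≤ 0.48, x ∈ [0.40, 0.60], z ≥ 0.62, angle ≤ 25°, bbox_x ≤ 30 mm, bbox_z ≤ 30 mm |
| intervertebral disc | V ≤ 8 mL, sphericity ≥ 0.40, x ∈ [0.30, 0.70], z ≥ 0.55, span ≤ 0.15 |
| renal pelvis/ureter | V ∈ [1, 15] mL, x ∈ [0.10, 0.38] or [0.62, 0.90], y ∈ [0.20, 0.60], z ∈ [0.60, 0.95] |

These intervals deliberately exclude mid-abdominal, anterior, winding
structures (bowel): equivalence with any other implementation's ranges is not
claimed, only functional behavior on phantoms (≥ 4/6 confounders removed,
≥ 95% of bowel volume retained under default conditions; in practice 6/6 on
most seeds).

## Refinement tools

The four interactive corrections are pure functions on one 2D slice, so a
batch edit script (JSON list of tool/series/slice/coordinates) reproduces any
refinement exactly.

Seeded add/remove minimizes the discrete Chan–Vese two-phase
piecewise-constant energy

E(C, c₁, c₂) = μ·Per(C) + λ₁ Σ_in (I − c₁)² + λ₂ Σ_out (I − c₂)²

with Per(C) the count of 4-adjacent label-discordant pixel pairs. The
minimizer is coordinate descent: exact updates of (c₁, c₂) alternate with
red/black checkerboard sweeps flipping every pixel whose flip strictly
decreases E. Same-color pixels are never 4-adjacent, so simultaneous flips
have independent perimeter effects and the energy is non-increasing at every
step — asserted per-iteration in the tests, not just hoped for. Defaults:
μ = 0.1, λ₁ = λ₂ = 1, ≤ 200 iterations, tolerance 1e-3, initialization a
3-pixel disk at the seed. μ = 0.1 is chosen so that a flat front advances
whenever the squared-contrast gain exceeds 2μ = 0.2 (front growth stalls for
larger μ on typical 0.8-contrast fluid); the remaining defaults follow common
practice for normalized images. After convergence the 8-connected foreground
component containing the seed is OR-ed in (add) or subtracted (remove); a
component exceeding 50% of the slice is treated as a leaked contour and the
edit is rejected with a warning, as are degenerate slices (indistinguishable
phases).

Regional add rasterizes the drawn polygon (even-odd rule on pixel centers,
via `skimage.measure.grid_points_in_poly`; simplicity validated with
shapely), computes the Kapur threshold from the in-polygon histogram only,
and adds in-polygon voxels above it. Regional remove clears in-polygon voxels
unconditionally.

## Volumetry

V(mask) = N_voxels × d_slice × d_row × d_col / 1000 mL, full floating-point
precision; display rounding only at the CLI. Per-slice curves are the same
quantity per slice and sum exactly to the total. ΔV = V_post − V_pre and may
be negative.

## Agreement statistics

ICC(2,1) (two-way random effects, absolute agreement, single rater) from the
ANOVA decomposition with rows = exams, columns = raters:

ICC = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE)),

with McGraw–Wong F-based 95% CI (Satterthwaite degrees of freedom; verified
against `pingouin.intraclass_corr` to 1e-9 on the estimate). Interpretation
bands: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent. A
useful identity for intuition: with k = 2 and columns of equal mean and
variance, the *consistency* coefficient (MSR−MSE)/(MSR+MSE) equals Pearson r
exactly; ICC(2,1) differs from it only by an O(1/n) absolute-agreement term.

Bland–Altman: mean difference of paired measurements with limits of agreement
mean ± 1.96 × sample (n−1) SD — the conventional normal-quantile limits, not
a t-quantile.

DSC = 2|A∩B|/(|A|+|B|); two empty masks are defined to agree perfectly
(DSC = 1, agreement on absence) rather than poisoning summary means — the
choice is logged in the docstring and trivially overridable by filtering.
Inference on DSC uses a paired two-sided t-test on logit(DSC) = ln(DSC/(1−DSC));
boundary values raise unless the caller opts into an explicit ε-clamp
(ε = 1e-6 suggested), never silently.

## Synthetic phantoms

The generator emulates the target acquisition: default 28 contiguous 4 mm
coronal slices, 160×160 at 0.8×0.8 mm, a tapered elliptic body of tissue
signal 0.25 containing bright fluid structures, Gaussian noise σ = 0.01, and
a secretory response of 55 mL (a typical pediatric-scale post−pre
difference). Bowel is 3 winding tubes (radius 5–7 mm, smoothed random walks)
in the mid-abdomen; the post series is identical except the tubes are grown
outward by a distance-ordered dilation (anisotropic EDT, deterministic raster
tie-break) until exactly the requested ΔV of voxels has been added —
preserving pre/post registration as matched acquisitions do. Confounders are
rendered at fixed anatomic slots with class-characteristic caricature
geometry matched one-to-one to the rule table (posterior midline canal
spanning 70% craniocaudally, a ladder of four oblate discs beside it, a large
inferior bladder, a right-upper gallbladder, a small branched paramedian
renal pelvis, and a thin bright shell at the body contour).

Two rendering choices matter for realism of the *histogram*, which is what
the thresholding stage sees:

- fluid intensity varies smoothly within each structure (a random linear
  gradient per structure spanning roughly 0.78–1.03 of the nominal fluid
  level), as in-vivo T2 fluid signal does; a single constant fluid level
  would concentrate the fluid class into one histogram spike and drag the
  entropy threshold into the tissue tail;
- structures keep ≥ ~6 mm mutual clearance (≥ 3 slices through-plane), so
  that above-threshold noise voxels cannot chain two structures into one
  26-connected cluster.

Ground truth is exact: reported true volumes are mask voxel counts × voxel
volume, and all masks are pairwise disjoint by construction. Everything is
deterministic per seed.

What the phantom does **not** model: Rician noise statistics, bias fields,
motion/respiratory artifacts, partial-volume fluid, anatomy beyond the
caricatures above. Passing phantom tests therefore demonstrates correctness
of the algorithms and their composition, not clinical segmentation accuracy.

Rater simulators support the statistics module: `simulate_raters` perturbs a
truth mask at its boundary (random toggles, strength found by bisection) to a
target mutual DSC ± 0.05; `simulate_rating_table` draws exam truths
N(μ, σ_b²) and rater values truth + N(0, σ_r²), giving population
ICC(2,1) = σ_b²/(σ_b² + σ_r²) for recovery tests.

## Problem sizes and numerical choices

The validation battery uses 20 noise-free phantoms (volume recovery ≤ 5%;
observed ≤ 0.1%), 5 noisy phantoms (confounder filtering), 1000 random
histograms (entropy oracle), 100 rating-table replicates at n = 200 (ICC
recovery and CI coverage) and 1000 null replicates at n = 20 (paired-logit-t
type-I error) — sizes at which every Monte-Carlo band in the tests is stable
across seeds. Degenerate inputs fail loudly and specifically: all-zero
volumes, single-bin histograms, constant rating matrices, boundary DSC
values, zero-variance paired differences, self-intersecting polygons.

## Known limitations

- The heuristic intervals are phantom-calibrated defaults, not clinically
  tuned values; real deployments should expect to edit the rule JSON.
- Seeded Chan-Vese on a seed placed in background segments the dark phase
  around the seed; the leak guard usually rejects this, but a small dark
  pocket enclosed by fluid can be added/removed as-is (matching what an
  interactive mis-click would do).
- Volumes on noisy data carry the attached-speckle film (~1–5% positive bias
  at default noise); it largely cancels in ΔV and is what interactive
  refinement exists to trim.
- No inter-series registration: inputs must be protocol-matched, and
  mismatched geometry is an error, not a warning.
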