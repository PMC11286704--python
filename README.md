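# pftquant

Quantification of secretin-stimulated bowel fluid volume from MR pancreatic
function tests (MR-PFTs).

MR-PFTs assess exocrine pancreatic function non-invasively: matched coronal
T2-weighted series are acquired before and ~15 minutes after secretin
administration, and the **secretory response** ΔV = V_post − V_pre (mL of
T2-bright bowel fluid) is the clinical metric. Measuring ΔV by hand —
windowing, thresholding and cleaning two full stacks per exam — is slow and
rater-dependent. `pftquant` implements the automated portion of a
semi-automated workflow for this task, plus everything needed to validate it
without patient data:

- **Automated candidate segmentation.** Both stacks are clipped at the
  99.999th pooled intensity percentile, rescaled to [0, 1], and thresholded at
  the cut `t*` maximizing the Kapur maximum-entropy criterion
  `H_below(t) + H_above(t)` on the pooled 256-bin histogram, where each class
  entropy is `−Σ qᵢ ln qᵢ` over its renormalized bin probabilities.
  Candidate clusters smaller than 1 mL are discarded.
- **Heuristic non-bowel removal.** 26-connected clusters are resampled to
  isotropic voxels; per-cluster morphometry (volume, normalized centroid,
  bounding box, sphericity `π^(1/3)(6V)^(2/3)/A`, principal-axis angle,
  craniocaudal span) is matched against an editable interval-rule table for
  six confounder classes: spinal canal, intervertebral discs, renal
  pelvis/proximal ureter, bladder, gallbladder and incompletely saturated fat
  at the body contour.
- **Scriptable refinement.** The four interactive correction tools as pure
  functions: seeded add/remove via a Chan–Vese two-phase piecewise-constant
  active contour, regional add via an in-polygon maximum-entropy threshold,
  and regional remove.
- **Volumetry.** V = voxel count × (slice thickness × row spacing × col
  spacing) / 1000 mL, with per-slice fluid-volume curves.
- **Agreement statistics.** ICC(2,1) with McGraw–Wong 95% CI and the
  conventional interpretation bands, Bland–Altman mean difference with
  1.96·SD limits of agreement, Dice similarity coefficient, and the paired
  t-test on logit-transformed DSC.
- **Synthetic phantoms.** An abdominal phantom generator with exact
  ground-truth masks for bowel and all six confounder classes, plus simulated
  raters (boundary-perturbed masks at a target mutual DSC; rating tables with
  a known population ICC), so the entire pipeline is testable end to end.

## Worked example

Generate a phantom exam (written as two DICOM series plus ground truth) and
run the automated chain on it:

```sh
$ pftquant phantom --out exam1 --seed 3
phantom written to exam1

$ pftquant run exam1/pre exam1/post --out result1
pre 32.7 mL  post 91.5 mL  delta 58.7 mL  -> result1

$ python -c "import json; print(json.load(open('exam1/truth.json'))['secretion_delta_ml'])"
54.999040000000015
```

The run report (`result1/report.json`) carries the measured volumes, the
per-slice fluid-volume curves, the threshold and clip value used, and the
classes of every removed non-bowel object; `pre_mask.nii.gz` /
`post_mask.nii.gz` are the final segmentations. Here the automated chain
recovers the phantom's true 55.0 mL secretory response as 58.7 mL — the
excess is above-threshold noise decorating the bowel surface, which the
refinement tools (or an edit script passed via `--edits`) would trim in
interactive use. On noise-free phantoms the recovery is exact to within
0.1%.

Agreement statistics from a ratings table (`exam_id,rater_id,delta_ml`):

```sh
$ pftquant agree --ratings ratings.csv --out report.json
ICC(2,1) = 0.899 (0.829-0.941), good
```

The same functionality is available as a library (`pftquant.run_exam`,
`pftquant.icc_2_1`, `pftquant.generate_phantom`, ...).

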