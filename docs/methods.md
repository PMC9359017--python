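# Methods

This note documents the models, conventions, parameter choices, and known
limitations of `e2eqa`. It states how quantities are computed; all numbers
shown in the README were produced by the code itself.

## Geometry and volumes

All volumes share an axis-aligned grid: 0-based indices, voxel-center
sampling, world coordinate `origin + index · spacing` (mm), axes
(X left-right, Y anterior-posterior, Z superior-inferior). Direction
matrices are restricted to identity: E2E phantom scans are acquired axially,
and supporting oblique grids would complicate warping for no benefit here.
Two geometries are considered equal within 1e-6 mm. MetaImage and NIfTI
files are read and written through SimpleITK; structure sets are stored as
one uint8 label map plus a YAML `{label: name}` table, which enforces the
shared-geometry invariant on load (overlapping structures such as CTV/PTV
must be written as separate mask files).

Margin expansion (`PTV = prostate + 5 mm`) is Euclidean in world space: a
voxel is inside the expansion iff its center lies within the margin of the
nearest inside voxel center, computed with a spacing-aware distance
transform. This matches clinical CTV→PTV margin semantics and is exact on
anisotropic grids.

## Gaussian deformations

The deformation model is a single isotropic Gaussian bump,
`d(r) = m · exp(−‖r−c‖²/(2σ²))` per axis. The printed "magnitude" is the
displacement at the center exactly; "standard deviation" is the falloff σ.
Sampling: center uniform in a 22.3 × 10.6 × 62 mm box anchored on the PTV
centroid (the anchor is configurable); one magnitude scalar uniform in
[10, 20] mm shared by the three axes with independent random signs (the
equal-|magnitude| pattern of the study parameter sets); σ uniform in
[15, 25] mm.

Warping uses the pull-back (resampling) convention of registration
toolkits, `output(x) = input(x + d(x))`, linear interpolation for images
and nearest-neighbor for masks, with out-of-grid samples taking the image
minimum (configurable).

Invertibility: the field's Jacobian is `I + A` with rank-1
`A = −(w/σ²) m(r−c)ᵀ`, so `det = 1 − (w/σ²) m·(r−c)`, minimized at
distance σ along `m`, where it equals `1 − |m| e^{−1/2}/σ`. Draws with
`|m| e^{−1/2} ≥ σ` — with equal per-axis magnitudes,
`√3 · |m_axis| · e^{−1/2} ≥ σ` — fold locally; this is reachable at the
extreme of the default ranges (per-axis 18.8 mm with σ = 15.6 mm is such a
case). The toolkit neither prevents nor repairs
folding — the E2E analysis needs a known applied field, not a
diffeomorphism — but `jacobian_determinant` exposes the check, and the test
suite pins the closed form.

## The surrogate of phantom and adaptive system

The real experiment images a rigid anthropomorphic pelvis phantom and runs
a vendor's proprietary auto-segmentation and re-optimization. The surrogate
reproduces the *observable structure* of that experiment, not the vendor
algorithms:

**Phantom.** Geometric primitives on a 128 × 128 × 96 grid at 2 mm
(≈ 26 × 26 × 19 cm): ellipsoid prostate (radii 22/20/18 mm), seminal
vesicles, bladder (anterior-superior), tubular rectum (posterior, radius
14 mm), a bowel region superior to the bladder, two 22 mm spherical femoral
heads, an elliptic-cylinder body. CTV = prostate ∪ seminal vesicles,
PTV = prostate + 5 mm. Tissue-class HU values with 15 HU Gaussian noise.
Positions only mimic pelvic topology; the analytics need plausible
adjacency and repeatability, not anatomical fidelity.

**Repeated segmentation.** Each simulated contour is the truth mask warped
by a smooth random displacement field: white noise Gaussian-filtered at a
correlation length of 8 mm, scaled to a per-axis standard deviation
`sd` (mm), applied by nearest-neighbor pull-back. `sd` is the single dial
for contour reproducibility. Defaults (mm):

| ROI | AI | corrected |
|---|---|---|
| Prostate | 2.5 | 1.2 |
| Seminal vesicles | 2.2 | 1.2 |
| Bladder | 2.2 | 1.0 |
| Rectum | 1.0 | 0.9 |
| Bowel | 0.5 | 0.5 |
| Femora | 0.4 | 0.4 |

Manual correction is emulated as the lower-noise regime for the target
structures and bladder (the structures that clinically need editing);
bowel and femora are left at the AI level. The values were chosen once so
the simulated variability lands in the regime reported for this workflow
(Dice > 0.93, mSSD < 1 mm for corrected contours, with AI-only contours
visibly worse for prostate/bladder/targets). CTV and PTV are derived from
the simulated prostate and seminal vesicles each fraction, which induces
the realistic correlation between target-structure errors.

**Dose.** A conformal surrogate, not an optimizer:
`dose = Rx · s · exp(−t²/(2p²))` where `t` is the Euclidean distance to the
PTV (0 inside), `p` the penumbra parameter, `s` a target-coverage scale,
plus smooth seeded noise of 0.15% Rx. Style defaults: IMRT p = 9 mm,
s = 1.004; VMAT p = 11 mm, s = 1.006. A narrower penumbra is what spares
normal tissue in a distance-falloff model, so the IMRT-like style gets the
narrower penumbra and the VMAT-like style the higher coverage scale,
reproducing the observed qualitative contrast (VMAT slightly better
coverage, IMRT slightly better sparing). Per-fraction dose variability
arises from re-simulating the segmentation-dependent PTV each fraction and
re-running the dose model with per-fraction seeds.

**Design.** 5 deformations × 26 fractions; per deformation, 13 IMRT + 13
VMAT fractions of which the first 3 per plan type are AI-only and the rest
manually corrected. All seeds descend from one master seed through a fixed
drawing order, so the whole study is reproducible bit-for-bit.

What the surrogate does *not* emulate: CBCT physics and artifacts,
registration failure modes, systematic (bias-like) segmentation errors,
optimizer trade-offs, inter-observer variation, intra-fraction motion.
Passing tests therefore validate the *analysis machinery* (metrics,
consensus, statistics, bookkeeping) under controlled conditions; they do
not certify any vendor system's accuracy.

## Metrics

Dice: `2|A∩B|/(|A|+|B|)`; two empty masks score 1 (perfect agreement on
absence). mSSD: surfaces are inside voxels with a face-adjacent outside
voxel (array borders count as outside); the metric is the pooled symmetric
mean — one mean over the union of both directed voxel-center distance
samples — computed exactly with spacing-aware distance transforms. The
pooled variant (rather than the average of the two directed means) is the
default because it weights each surface point equally; the two differ only
for unequal surface counts. Distances are 3-D; no sub-voxel meshing or
slicewise contouring is attempted, which keeps the metric reproducible
across grids at the cost of sub-voxel accuracy.

STAPLE: classical EM. E-step: per-voxel posterior foreground weight from
the current per-rater sensitivities/specificities and the foreground prior;
M-step: re-estimate each rater's (p, q) from the weights. Initialization
p = q = 0.99, prior = mean foreground fraction of the inputs (`auto`),
convergence when the mean absolute weight change < 1e-6 (cap 100
iterations; non-convergence is flagged, not raised), consensus = weight
≥ 0.5 with ties counting as foreground. Estimates are clipped to
[1e-7, 1−1e-7] to keep the E-step finite. With `max_iter = 0` and prior
0.5 the E-step reduces to a voxelwise majority vote, which the tests pin
against a vote oracle. Within the comparison pipeline STAPLE runs on the
padded union bounding box of each repetition group; this leaves the
consensus unchanged in practice while keeping EM small, and the reported
specificities then refer to that neighborhood rather than the full grid.

## DVH engine

Cumulative DVHs with 0.05 Gy bins; `fraction(d)` = proportion of mask
voxels with dose ≥ d, linear interpolation between edges. D_v is read off
the curve where it crosses v/100 (so it is exact to curve resolution, ≤ one
bin); V_d at bin-aligned doses is exact. Dmax is the point maximum voxel
dose — the simplest reproducible convention — with a near-maximum
D0.03cc variant available. Percent-of-Rx limits are evaluated against the
total-course prescription (70 Gy); a per-fraction prescription can be
passed instead. Achieved values are stable to < 0.1% under bin refinement
below 0.1 Gy.

## Statistics and the pooling rule

One-way fixed-effects ANOVA from explicit sums of squares, p from the F
distribution; degenerate within-group variance yields a flagged result with
p = NaN. For each ROI and correction mode the groups are the deformation
instances (plan types and fractions pooled within group, matching the
repetition-set definition). Pool iff p ≥ α (default 0.05): the action
level is then one 95% interval over all fractions × deformations;
otherwise the ROI is flagged and intervals are reported per deformation.
Dose-volume constraint values are always stratified by plan type, because
the two styles differ systematically, with deformations pooled within plan
type. No multiplicity correction is applied across ROIs — raw p values are
reported and the α is configurable — mirroring standard practice for this
kind of commissioning report. ANOVA on mSSD uses the same machinery.

Intervals: empirical 2.5/97.5 percentiles (interpolated order statistics)
by default; normal-theory mean ± 1.96 sd as an option. Endpoints are
clipped to the metric domain ([0, 1] for Dice, ≥ 0 for mSSD). Percentile is
the default because Dice distributions near 1 are strongly skewed.

## Problem sizes and numerical choices

The default virtual study (5 × 26 fractions, 8 ROIs, 128 × 128 × 96 grid)
runs in about two minutes on one CPU; segmentation simulation and surface
metrics operate on padded bounding boxes, which is exact (the padding
bounds the maximum displacement, and both surfaces lie inside the union
box). The test suite uses a coarser 64 × 64 × 48 / 4 mm phantom for
pipeline tests and 10–16³ grids for oracle comparisons; brute-force
all-pairs oracles back every metric and DVH quantity at these sizes.
Tie-breaks and degenerate inputs are fixed deterministically throughout
(STAPLE weight 0.5 → foreground; both-empty Dice = 1; empty masks are
rejected where a metric would be undefined). Doses are float64 Gy;
comparisons TSVs are written with pandas' default float formatting, which
is what makes repeated runs byte-identical.

## Known limitations

- Voxelized surfaces bias mSSD low by up to about half a voxel relative to
  sub-voxel surface models; all reported distances share this convention.
- The dose surrogate has no beam model; its action levels exercise the
  reporting machinery and are not transferable to a clinical system.
- The segmentation noise model is unbiased (random perturbation around
  truth); systematic auto-segmentation errors would shift consensus and
  truth together and are invisible to a repeatability analysis by design.
- Only axis-aligned geometries; DICOM RTSTRUCT/RTDOSE are out of scope
  (convert to MetaImage/NIfTI label maps first).
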