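# Methods

## Problem and coordinate conventions

The package aligns serial whole-mount histopathology sections of a resected
prostate with the patient's presurgical T2-weighted MRI, slice by slice,
assuming an expert-supplied correspondence between each section and one
axial MRI slice. All computations are carried out in physical millimetres:
a pixel at array index `(row, col)` sits at `(col·sx, row·sy)` with origin
zero, spacing always comes from image headers or sidecar metadata, and no
operation ever interprets a pixel index as a distance. Transforms follow the
ITK resampling convention (a transform attached to a registration with
fixed image F maps F-frame points to moving-frame points); per-slice results
are stored as the triple rigid/affine/deformable, where the composite
histology→MRI point map is `affine(deformable(rigid⁻¹(p)))`.

## Registration pipeline

**Reconstruction.** Sections are stacked by chaining pairwise registrations
outward from the middle section (index `floor(D/2)`, 0-based), each section
registered against its neighbour's mask already resampled into the
reconstructed frame, so the middle section anchors the frame exactly and
pairwise errors do not compound a neighbour's original misalignment. The
pair similarity is the sum of squared differences between the binary
prostate masks — robust to stain and intensity differences between adjacent
sections. The pair pose is estimated as a *similarity* transform whose scale
is then discarded: adjacent sections differ in area through the gland's
apex/base taper, and letting a scale parameter absorb that difference
removes a rotation bias (up to ~10° on strongly tapered outer sections)
that a rigid-only fit exhibits. The returned transform is rigid.

**Initialization.** Plain gradient descent cannot recover mounting
rotations of 10–30° from a centroid-aligned start: the mask-SSD landscape
has a shear-compensated local optimum in which overlap is high but the
rotation is wrong. Every mask registration therefore starts from a
moment-based similarity initialization: centroids aligned, scale set from
the mask-area ratio (affine stage only), and the rotation chosen by a
coarse-to-fine exhaustive SSD search (3° steps over ±90° on 4× downsampled
masks, then 0.25° steps in the winning 6° window at full resolution). The
search is deterministic and costs a few milliseconds per slice.

**Affine stage.** From that initialization, a full 2D affine is refined by
gradient descent (learning rate 0.01, 250 iterations per pyramid level,
parameter scales from physical shift) minimizing SSD between the binary
prostate masks over a three-level pyramid (shrink factors 16/8/4, smoothing
sigmas 4/2/1 pixels). Grayscale intensities never enter this stage. A
degenerate result (|det| < 1e-3) is clamped back to the initializer.

**Deformable stage.** A cubic free-form B-spline displacement field with a
6×6 control-point grid is optimized under Mattes mutual information (32
bins, dense sampling — hence fully deterministic) with an LBFGSB optimizer,
10 iterations per pyramid level. The control grid is kept fixed across
levels because LBFGSB's box constraints are sized once and cannot follow a
growing parameter count; those box constraints double as the stiffness cap,
bounding each displacement component so the field magnitude stays below
10% of the image width. By default the stage sees the masked luminance
(0.299/0.587/0.114) conversion of the histology against the masked MRI
slice. The optimized field is accepted only if (a) mutual information
improves on the affine-only value and (b), when prostate masks are
available, mask overlap does not decrease — the second guard keeps the
stiff deformable stage from trading boundary agreement for histogram
effects on already well-aligned slices; wherever real deformation exists
(e.g. endorectal-coil-like compression) the field improves overlap and is
kept. On rejection or optimizer failure the affine-only result is returned
with a warning.

**Mapping.** Points (landmarks) map histology→MRI through the forward
composite, which needs only the analytic rigid inverse. Resampling labels
onto the MRI grid needs the opposite direction, so the B-spline is inverted
by fixed-point displacement-field iteration (tolerance 0.1 px, max 50
iterations) and the whole composite is applied in a single
nearest-neighbour pass — no intermediate resamplings, so interpolation blur
is not compounded and no label value absent from the input can appear.

## Evaluation metrics

Slice-averaged Dice of the prostate masks; slice-averaged symmetric
Hausdorff distance between the 8-connected boundary pixel centres, in mm;
mean Euclidean distance between identically named landmark centres of mass;
and urethra centre-of-mass deviation averaged over the slices where the
urethra is visible on both modalities. A slice where both masks are empty
contributes Dice 1 (vacuous agreement at tapered apex/base sections),
asymmetric emptiness contributes 0; Hausdorff is undefined (an error) when
exactly one mask of a pair is empty. The Hausdorff is the classic
max-of-sup-infs, not a percentile variant.

## Digital phantom

The phantom emulates the data this pipeline consumes while keeping exact
ground truth. A continuous anatomy model — prostate ellipsoid of semi-axes
25 × 20 × 24 mm, posterior peripheral-zone band, 1.6 mm-radius urethra tube
tilted 0.5 mm/mm in x so out-of-plane offsets displace it visibly, and a
7 mm-radius cancer ball in the posterior lateral gland — is sampled on a
256² grid at 0.4 × 0.4 × 4.0 mm (six slices). The prostate cross-section is
an *egg* profile (anterior semi-axis × 0.80, posterior × 1.15), as in vivo
glands are flatter anteriorly; this matters methodologically, because a
pure ellipse can be mapped onto any rotated copy of itself by an affine
without rotating, which would make rotation-recovery experiments
meaningless.

MRI voxels get the per-region mean intensity (background 40, central gland
120, peripheral zone 200, cancer 80, urethra 230 — the T2w contrast
ordering) plus i.i.d. Gaussian noise; histology pixels get per-region RGB
means (H&E-like pinks/purples on a white slide) plus per-channel noise. The
default noise s.d. of 4 is 5% of the prostate/background MRI contrast.
Histology is rendered on the MRI slice grid, so with no injected artifacts
the correct registration is exactly the identity — a clean test anchor.

Artifacts are injected per section with recorded ground truth: rotation
drawn uniformly from [-r, r] about the slice centre; isotropic scaling by
1-s; translation drawn uniformly within ±5% of the image width in x *and*
y, applied only alongside shrinkage (rotation-only conditions stay
untranslated, matching how fixation shrinkage and specimen handling occur
together); optional left–right flip. Artifact application is purely
geometric and noise is drawn afterwards, so corrupted sections carry fresh
rather than resampled noise. The imperfect-correspondence condition samples
the histology 2 mm away along the slice axis from its paired MRI slice.
Three point landmarks per slice (urethra centre, cancer axis, and an
off-centre anchor that follows the taper) propagate through the artifact
transforms exactly.

What the phantom does **not** model: glandular texture, stain variability,
tissue tearing/ripping (not correctable by registration), quadrant
stitching artifacts, and genuinely non-rigid fixation deformation. Passing
the phantom study therefore demonstrates geometric recovery of the modelled
artifact classes, not performance on real H&E appearance.

## Experiment design and problem sizes

Condition sweeps repeat each condition with distinct seeds derived from a
`SeedSequence` of (base seed, condition index, repetition), so every case is
independent yet exactly reproducible; a failed registration is recorded as
a failed row, never a crashed sweep. The bundled experiments run the
headline conditions at full scale — rotation r ∈ {5, 10,
15, 20}° and shrinkage up to 10% at 10 repetitions, 256² resolution — and a
48-condition grid (rotations to 40°, shrinkage to 30%, both correspondence
settings) at 3 repetitions on a half-resolution phantom (128² at 0.8 mm,
same field of view), which we chose to keep the default validation run in
the minutes range on a single CPU.

## Numerical choices and edge cases

- Linear interpolation for images, nearest-neighbour for masks and labels.
- Fixed iteration budgets (250 affine / 10 deformable per level), no early
  stopping, for bit-reproducibility.
- Pair/affine fallbacks guarantee monotone improvement: if the optimizer
  result lowers mask Dice below the initializer's (or the identity's), the
  better candidate is returned and the convergence flag cleared.
- Empty masks raise errors naming the offending input or slice; a phantom
  spec whose geometry leaves any slice without prostate is rejected at
  construction, naming the slice.
- Angle recovery is reported as the rotation part (polar decomposition) of
  the composite map's local Jacobian at the gland centre; using a single
  direction vector instead would alias affine shear into the angle.

## Known limitations

- Rotation recovery relies on mask asymmetry. Near-circularly-symmetric
  glands leave the angle weakly determined for the mask-only affine stage;
  the deformable stage does not correct global rotation.
- The reconstruction's rigid chain has a small taper-induced angle bias on
  strongly tapered outer sections (≤0.6° at working resolution); the
  per-slice affine against the corresponding MRI slice absorbs it.
- Out-of-plane (z) alignment is out of scope: slice correspondence is
  an input assumption, and 3D slice-crossing deformable registration is
  deliberately avoided.
- The B-spline inverse is approximate (fixed-point); points can fail to
  invert near the domain boundary and are then dropped with a warning
  during landmark mapping.
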