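# Methods

## Problem and model

The package quantifies how two cardiac cell populations — striated
myocytes and fibroblasts — organize in a strained co-culture, from
three-channel fluorescence images. Cellular orientation is carried by
actin fibrils, which both cell types express; attribution of actin to a
cell type comes from the α-actinin channel: α-actinin with periodic
sarcomeric z-lines marks a mature striated myocyte, α-actinin without
striations marks an immature/"Other" cell, and actin without α-actinin
marks a fibroblast. Background carries neither stain.

Orientation is axial (defined modulo 180°). All orientation statistics go
through the mean dyadic tensor of unit axial vectors
T = ⟨r rᵀ⟩, r = (cos θ, sin θ). T is symmetric with unit trace; its
largest eigenvalue λ lies in [½, 1]. We report the normalized
orientational order parameter OOP = 2λ − 1 so that 0 is isotropy and 1
perfect alignment, with `oop_convention="raw_eigenvalue"` available for
the literal eigenvalue. The director is the eigenvector of λ, reported in
[0°, 180°); angles between axes fold through arccos|p·q| into [0°, 90°].
The per-vector dyadic tensor is averaged over the vector multiset, making
the OOP invariant under duplication and global rotation.

Coordinate convention, used everywhere: arrays are (row, col); an angle θ
denotes the axis (cos θ, sin θ) in (x = col, y = row) components.

## Pipeline stages and defaults

**Texture features.** The α-actinin image is standardized per image with
median/MAD (the robust location/scale anchors the background mode of the
intensity distribution, so images that differ only in signal content
still agree on what background looks like; mean/sd standardization
stretches a signal-free image's noise to unit variance and makes its
background look foreground-like). Four planes: local entropy (9×9, on
intensities quantized to 256 gray levels), local standard deviation
(5×5), local range (5×5), Gaussian-smoothed intensity (σ = 5). Borders
reflect. Window sizes are analysis choices exposed in `TextureParams`.

**Training.** Pixels are subsampled at `floor(0.025 · H · W)` per image
(34,406 for a 1024×1344 field), split equally across classes; exhausted
classes are sampled fully with the shortfall recorded. The decision
tree's depth and leaf size are chosen by a seeded 5-fold cross-validated
grid search over depth {4, 6, 8, 12, 16} × leaf {1, 5, 20, 100}. The
fitted tree is serialized as plain JSON arrays and predictions traverse
those arrays directly, so a reloaded model is bit-identical in behavior.
The three-way manual annotation collapses to Background vs Foreground at
this stage; striated-vs-other is resolved structurally downstream.

**Striation detection.** The α-actinin image is smoothed by Perona–Malik
anisotropic diffusion (15 iterations, time step 0.15, exponential
conductance with contrast at the 80th percentile of gradient magnitude;
the explicit scheme at dt ≤ 0.25 obeys the maximum principle), then
white-top-hat filtered with a disk of radius 4 px — half the expected
z-line spacing, which sets the natural scale. Two binarizations of the
same top-hat image: adaptive (pixel > local 25×25 mean + offset, offset
defaulting to 10% of the top-hat maximum — low enough to keep faint
z-lines, high enough that neighbouring stripes do not bridge through dim
inter-stripe ridges) and global (Otsu on nonzero pixels). Adaptive-mask
objects under 9 px are discarded as speckle: a genuine z-line crosses the
myocyte width and spans tens of pixels.

**Object orientation.** Each foreground pixel needs the axis of the cell
it belongs to. The α-actinin image is smoothed with σ = 5 (washing out
striation-scale detail) and the ridge-orientation estimator is run with a
56-px window — wide enough to span a cell body, so the dominant gradient
crosses the cell's long sides and the ridge axis is the cell axis, yet
local enough that touching cells with different axes keep their own
orientations (a single per-component shape axis fails exactly there).
Pixels failing a low coherence cutoff (0.02) inherit the nearest valid
estimate.

**Superpixel decision.** ~200 SLIC superpixels (compactness 0.1; SLIC is
deterministic, the seed argument is recorded for interface stability).
Superpixels with < 10% foreground are Background and decisions use
foreground pixels only (the denominator choice is switchable). Each
striation component (≥ 3 px) gets its principal axis from second moments;
a component is "perpendicular" when |dot| < 0.8 between its axis and the
axial mean of the object orientation over the component — on unit axial
vectors, so the test is sign-free; 0.8 corresponds to ≈ 36.9°. A
foreground superpixel is StriatedMyocyte iff perpendicular-striation
coverage ≥ 10% and global-mask coverage ≥ 5%; otherwise Other.

**Orientation field.** Actin orientation per pixel: Gaussian smooth
(σ = 2), z-score, Sobel gradients, structure-tensor sums over sliding
8-px windows; ridge axis = 90° + ½·atan2(2ΣGxGy, Σ(Gx²−Gy²)); validity
requires gradient coherence ≥ 0.2. A border margin of
block/2 + 3σ + 1 px is invalidated: reflection padding mirrors
orientations across the border and produces systematic errors there.

**Cell-type vector selection.** Cardiomyocyte vectors: valid field pixels
classified StriatedMyocyte. Fibroblast vectors: valid pixels in the actin
foreground whose α-actinin class is Background. Other-class pixels count
in the denominator of the actin fraction but belong to neither
population. The actin-foreground requirement applies to every class
alike — an actin orientation vector only exists where actin is present;
without this symmetry the α-actinin halo around myocytes inflates the
cardiomyocyte fraction. Actin foreground defaults to Otsu on the smoothed
actin channel; a classifier trained on actin-channel images can be
substituted.

**Angle to stretch.** The stretch axis is a configuration unit vector
(default along +x; `--stretch-angle` accepts degrees), compared with each
director by the folded arccos.

**Pooling.** Multiple fields of view of one well are pooled at the vector
level before the OOP is computed (the OOP is a property of the vector
distribution, not a per-field average); a per-field-mean alternative is
available in the experiment runner.

**Log-normal fit.** y = y₀ + a·x·exp(−½ (ln(x/x₀)/b)²) for x > 0, fitted
by unconstrained Levenberg–Marquardt. Initialization: y₀ ← max y, x₀ ←
argmin of smoothed y, a ← (min y − max y)/x₀, b ← 0.35. Points at x = 0
(wells with no cardiomyocyte actin) are excluded with a recorded count.
Standard errors and p-values come from the Jacobian at the solution
(asymptotic t theory); R² = 1 − SSres/SStot, reported NaN when SStot = 0.
For a < 0 the curve has a unique interior minimum at x₀·exp(b²).
Identifiability note: with coefficients of the magnitude reported for
cardiac co-cultures (a ≈ −0.16, y₀ ≈ 0.74) the curve's total dynamic
range is ≈ 0.07, so at noise σ = 0.02 individual coefficients carry
relative standard errors near 10% — coefficient-recovery benchmarks at
that noise level therefore use a strongly expressed peak
(a, b, x₀, y₀) = (−1, 0.35, 0.45, 0.9), where recovery within 10% is
statistically meaningful.

**Nucleus labeling.** Instance maps come from an external segmenter; a
simple Otsu + distance-transform watershed fallback covers synthetic
fixtures. Each nucleus takes the modal class over its pixels iff the mode
covers ≥ 0.4 of the nucleus; exact ties leave it unassigned
(conservative).

**Group statistics.** One-way ANOVA and Tukey's HSD over experiment
groups are delegated to scipy/statsmodels, significance at p < 0.05.

## Synthetic tissue generator

Scenes emulate sub-confluent monolayers on a 256×256 grid by default.
Cells are rotated ellipses with a flat-top envelope ((1 − ρ²)^¼: uniform
interior, crisp few-pixel rim, as in a stained cell body) carrying
multiplicative fibril texture — smooth 1-D noise across the axis, so
fibrils elongate along it. Myocyte α-actinin is modulated by a sinusoid
along the axis (period 8 px, contrast 0.5 by default): stripe normal
parallel to the axis, z-lines perpendicular to it; a
`striations_parallel` switch generates control cells whose striations run
along the axis and must never classify as striated. "Other" cells show
fibrous, unstriated α-actinin. One elliptical nucleus per cell. Noise is
additive Gaussian clipped at zero (default sd 2 against signal level 10,
i.e. SNR 5); Poisson shot noise is available but off. Placement is
low-overlap (candidates rejected above ~5% overlap, 60 tries): overlap
was rare in the monolayer cultures this emulates, and it keeps the
ground-truth maps unambiguous. Type composition is drawn per cell, so
realized per-well fractions fluctuate binomially around the target as
real seeding ratios do.

What the generator does *not* emulate: optical PSF and depth blur,
non-uniform illumination, staining variability, cell shape irregularity,
overlapping/stacked cells, and the full density range of confluent
tissue. Passing the synthetic benchmark therefore demonstrates the
internal consistency and geometric correctness of the pipeline — class
separation, orientation recovery, fraction accounting — not its accuracy
on real micrographs, which depends on texture statistics the generator
idealizes.

## Benchmark problem sizes

The test-suite and acceptance benchmarks use 256×256 scenes with 5–6
cells per well, 6 training images, 12–20 evaluation scenes, and
composition sweeps of {0, 0.25, 0.5, 0.75, 1} × 2–3 wells; these sizes
give stable statistics (superpixel recalls estimated over ≥ 70 tiles,
orientation recovery over > 10⁵ pixels) while keeping any single run in
seconds.

## Known limitations

- Regions, not cells, are classified: a single disorganized cell and
  several well-organized but differently oriented cells are
  indistinguishable.
- Overlapping cells of different types are resolved by draw order in the
  generator and are not resolvable by the classifier.
- The superpixel decision is all-or-nothing per tile; mixed tiles at cell
  boundaries contribute boundary error of a few percent to the actin
  fraction.
- The striation rule's dot-product threshold (0.8) tolerates up to ≈ 37°
  of obliquity; strongly curved myocytes with locally oblique z-lines may
  fall below the perpendicular-coverage threshold.
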