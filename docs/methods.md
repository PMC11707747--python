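# Methods

This note documents the models, algorithms and design choices behind
`afstain`, and what its synthetic-phantom experiments do and do not
establish about real tissue.

## The problem

Virtual staining maps a hyperspectral autofluorescence (AF) scan of an
unstained tissue section to one or more stain images — routine H&E, or a
multiplex immunofluorescence (mIF) panel of DAPI (nuclei), PanCK
(epithelial tumor), PD-L1 (immune checkpoint ligand), CD3 (T cells) and
CD8 (cytotoxic T cells) — without consuming the section.  The toolkit
implements the computational stages of such a system: data alignment and
quality control, pseudo-IHC rendering, paired patch sampling, the
generative stainer and its losses, and the quantitative evaluation of
real-vs-virtual agreement.  Clinical slide data are unavailable, so all
experiments run on synthetic phantoms with exact ground truth.

## Synthetic tissue phantoms (`afstain.phantom`)

A phantom is a set of disk nuclei (Gaussian-blurred edges) with per-cell
marker expression, placed by rejection sampling with a minimum
separation inside a smooth tissue blob; a smooth sub-blob is the tumor
region.  Expression follows the panel's biology: PanCK > 0 iff the cell
is tumor-class, CD3 > 0 for all T cells, CD8 > 0 for the cytotoxic
subset, PD-L1 on configurable fractions of tumor and immune cells.
Renders:

* **mIF** — DAPI disks at nuclei; membrane/cytoplasmic marker disks
  (1.6× nuclear radius); PanCK additionally fills the whole tumor
  region at a membranous base level; the residual-AF channel is an
  attenuated copy of total emission; all channels share one PSF
  (Gaussian, σ = 1 px default).  CD8 optionally receives a nonspecific
  background: a smooth low-frequency field plus sparse speckle over the
  tissue, emulating the background fluorescence that inflates CD8 false
  positives.
* **AF** — 20 channels as a sum of per-compartment occupancy maps
  (stroma, nuclei, tumor cytoplasm, immune cytoplasm) times compartment
  emission spectra.  No quantitative spectra are known for tissue
  classes, so the defaults are smooth Gaussian bumps at distinct
  channels — free parameters chosen to be separable by linear unmixing,
  which the tests exploit as an oracle.
* **H&E** — Beer–Lambert absorption with standard hematoxylin and eosin
  optical-density vectors; nuclei blue-purple, stroma pink, background
  white.

Magnification convention: 40× = 0.25 μm/px, 10× = 1.0 μm/px, stored as
pixel size in image metadata; every μm threshold converts through it.

Warping fixtures: pure translations (sub-pixel via spline resampling)
and compact local warps whose displacement field is flat over the inner
half-radius and tapers by a raised cosine to exactly zero at the stated
radius — pixels outside the support are bitwise unchanged.

All generation and rendering is bitwise-deterministic for a fixed seed.

**What the phantoms do not model:** real AF spectra and their
within-class variability, chromatic aberration and scanner optics,
staining chemistry, cell morphology beyond disks, spatially correlated
expression patterns.  Tests passing on phantoms establish algorithmic
correctness (contracts, invariants, closed-form agreement), not
performance on tissue.

## Pseudo-IHC rendering (`afstain.pihc`)

Three mIF channels (DAPI → hematoxylin-like, target marker → DAB-like,
residual AF → gray tissue background) are mapped pixel-wise through

    rgb = offset + white · exp(−M a),   a_k = clip(raw_k / norm_k, 0, 1)

where the columns of the 3×3 matrix `M` are unit stain optical-density
directions scaled by per-stain absorbance ceilings.  Defaults use the
standard stain-deconvolution hematoxylin (0.65, 0.70, 0.29) and DAB
(0.27, 0.57, 0.78) directions and a weak gray background column; the
color `offset` reproduces the cast of real brightfield scans.  The
inverse is exact algebra on the un-clipped range; out-of-domain pixels
(transmittance ≤ 0 after offset removal) are clamped and counted with a
warning.  Multiplex overlays sum the members' optical densities, each
scaled per RGB channel by its pseudo-color, so the identity color
(1,1,1) passes a single image through unchanged.  The background term is
a third absorbance column (not a multiplicative transmittance factor);
with the published constants unavailable, every constant is
configuration.

## Registration and warping QC (`afstain.registration`)

**Distance metrics.**  NGF is the squared edge-orientation alignment,
`d(a,b) = Σ_px [1 − (∇a·∇b)² / ((|∇a|²+ε²)(|∇b|²+ε²))]`, with
ε = 0.01 of the [0,1] intensity range; the squaring makes it insensitive
to contrast inversion, as required for AF-vs-stain comparison.  NTG is
`Σ|∇(a−b)| / (Σ|∇a| + Σ|∇b|)`.  Note `d(a,a)` is not zero — flat
regions contribute a full term — so alignment quality is judged by a
masked residual over edge pixels.

**Local translational score.**  Patch pairs are converted to grayscale
and normalized to [0,1].  Coarse-to-fine over a 3-level Gaussian
pyramid, the metric is evaluated at exact integer shifts of the second
patch (pure array slicing — no resampling, hence no interpolation
bias), the minimizing integer shift warm-starts the next level, and at
the finest level the minimum is refined to sub-pixel precision by
Powell search on a bicubic fit of the sampled landscape.  An earlier
variant that ran Powell directly on spline-resampled images showed
texture-dependent ±0.1 px bias; the landscape formulation brings the
error to a few hundredths of a pixel across phantom seeds.  The score —
the recovered translation magnitude times the pixel size, i.e. μm at
the 10× reference — is reported at 0.1 μm resolution, coarser than the
estimator's error, so threshold decisions are stable.  A region is
**misaligned iff score > 6 μm** (strict: exactly 6 μm is retained).
NGF and NTG produce the same decisions on the phantom warp suite.

**Global affine.**  Six-parameter affine registration, Powell per
pyramid level with warm starts (translations doubled between levels).
The internal cost is a magnitude-free variant of NGF restricted to edge
pixels of the fixed image — the ε-regularized sum rewards gradient
steepening (a slight spurious zoom) and weak-gradient noise, whereas
the orientation-only form has its optimum at true alignment.  Powell's
result replaces the warm start only when strictly better, so identical
inputs return the identity transform exactly.  Failure (edge-pixel NGF
residual above 0.3) flags the pair for exclusion.

**Exclusion mask.**  The aligned pair is tiled (256 px at 10× with 50%
overlap by default); each tile is scored and a pixel is excluded when
any covering tile exceeds the threshold.

## Patch sampling (`afstain.sampling`)

Pairs are sampled at 40× from identical locations; the stain patch is
the AF patch padded by 16 px per side (full scale: 128×128×20 AF,
160×160×C stain).  Sampling weight is 1 on tissue (Otsu threshold on
smoothed total intensity, morphologically cleaned, scale-invariant),
multiplied by 3 inside the PanCK-positive region and by 3 inside the
PD-L1-positive region (Otsu on the smoothed channel; both factors
configurable — only "higher probabilities" is prescribed), and 0 inside
the warping-QC exclusion mask.  Desk-scale default counts are ≤ 10⁵
pairs; the production-scale tens of millions are out of scope.

## The stainer (`afstain.stainer`, `afstain.nn`)

A pix2pix-style conditional GAN.  The U-Net generator (configurable
depth, base filters, kernel size; Glorot-uniform init) maps AF patches
to stain patches; one conditional discriminator sees AF concatenated
with the stain, and two unconditional discriminators see the stain at
full and half scale.  All networks run on an in-repo NumPy reverse-mode
autodiff engine (im2col convolutions, float64), which makes every run
bit-reproducible for a fixed seed on one CPU.

Losses:

* **Shift-invariant weighted regression** — minimum over all integer
  crop offsets of the padded target of the weight-normalized mean L1 +
  mean L2; the 16-px pad absorbs residual local misalignment of up to
  16 px per axis exactly.  The search is exhaustive (numba-accelerated
  when available); the gradient flows through the loss at the chosen
  offset.
* **Pixel weighting** — `w = max(1, log(min(i, i_max)))` on the raw
  target-stain IF intensity, natural log by default (base
  configurable); for CD8, all pixels with intensity below 15 get
  weight 1, suppressing label noise from nonspecific background.
  Uniform weights reduce exactly to the unweighted loss.
* **Rotational consistency** — mean L1 between `G(x)` and
  `rot⁻¹(G(rot(x)))` for a 90°/180°/270° rotation (training cycles the
  three deterministically; averaging is available).
* **Adversarial** — non-saturating cross-entropy per branch, weighted
  and summed; the half-scale branch downsamples by factor 2.
* **L2 regularization** on generator weights.

Training uses Adam with step-keyed piecewise-constant learning-rate and
loss-weight schedules, periodic validation (L1 against the center crop
plus a Fréchet distance in feature space), and in-memory checkpoints.
The Fréchet distance is the Gaussian closed form
‖μ₁−μ₂‖² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^{1/2}) on sample moments, with diagonal
regularization (logged) when a covariance is singular; the feature
extractor is pluggable and defaults to a fixed-seed random projection of
flattened patches — appropriate at desk scale, where no pretrained
embedding network is assumed.  Checkpoint selection minimizes the rank
sum of validation L1 and Fréchet distance, ties to the earlier step.
NaN/Inf loss aborts with a diagnostics snapshot.

WSI inference tiles the image with cosine-feathered overlaps; a single
tile covering the input is exactly one generator pass.  The U-Net is
not exactly shift-invariant, so different tilings agree only within a
blend tolerance in the interior.

Desk-scale problem sizes used throughout the tests: 64-px patches,
8-pair training sets, 200-step runs, base 8 filters at depth 2 — chosen
so the convergence and determinism properties are demonstrated in
minutes on one CPU.  Such runs demonstrate that the losses, gradients
and training loop are correct; they say nothing about attainable stain
quality at production scale.

## Quantification (`afstain.quantify`)

A stand-in for classic threshold-based commercial image analysis, built
from standard primitives: cells are segmented from smoothed DAPI
(threshold → distance transform → peak markers → marker-controlled
watershed, splitting touching nuclei); tumor regions from smoothed
PanCK at half the Otsu threshold (plain Otsu splits between the
membranous region level and bright cell bodies) with small-object and
hole removal.  A cell is positive for PD-L1/CD3/CD8 when its mean
intensity in that channel reaches the marker threshold — explicit
config values, no auto-tuning.  Cells belong to the tumor by centroid
membership.

Per ROI — whole tissue, *real tumor* (the real PanCK mask applied to
both sides), or *respective tumor* (each side's own mask):
PanCK-positive area (mm²), cell densities (cells/mm²), positive-cell
percentages (not reported for DAPI, whose denominator it would be),
TPS, CPS (immune cell = any non-tumor segmented cell; capped at 100 per
clinical convention), and CD3∧CD8 / CD3∧PD-L1 colocalization counts,
densities and percentages.  An ROI with no tumor cells yields an
explicitly undefined TPS/CPS with a reason, never a silent zero.

## Concordance (`afstain.concordance`)

Dice = 2|A∩B|/(|A|+|B|); both-empty is defined as 1.0 (logged
convention), empty-vs-nonempty as 0.  Label maps use a 9-category
vocabulary (six LUAD tumor subtypes, leukocyte aggregates, necrosis,
other); the combined-tumor merge collapses the six subtypes and
conserves pixel mass, and the LUAD-5% rule keeps cases where a subtype
strictly exceeds 5% of total tumor area.  The histologic-subtyping
network itself is consumed as label maps, not re-implemented.  Paired
measurement sets are summarized per measurement and ROI by the sample
Pearson r with a Fisher-z 95% CI and the mean absolute difference;
undefined entries drop pairwise with counts reported, and exact
agreement reports r = 1.0 without float jitter.

## Numerical and degenerate-input conventions

Coordinates are pixel-centered, origin top-left, x = column, 0-based,
half-open crops.  Strict inequalities: QC exclusion (> 6 μm), LUAD-5%
(> 5%).  The pIHC inverse clamps out-of-domain pixels and reports them.
`pearson_ci` refuses vectors shorter than 4 or with zero variance.
Blank images yield empty masks/tables with warnings rather than errors.
Packing infeasibility in the phantom raises an explicit error.

## Known limitations

* Phantom realism is deliberately minimal (disks, two-compartment
  optics, free-parameter spectra).
* The global affine search is local (Powell); very large initial
  misalignments beyond the pyramid's capture range will flag as failed
  rather than recover.
* The Fréchet default embedding is a random projection, suitable for
  monitoring convergence, not for comparing against published distances
  computed with pretrained networks.
* Training at paper scale (tens of millions of patches, 10⁵–10⁶ steps)
  is out of scope for the NumPy engine; the architecture is sized for
  correctness demonstrations.
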