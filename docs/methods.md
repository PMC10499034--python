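# Methods

This document records the measurement models, the synthetic-data model, and
the numerical choices behind `ciliaquant`.

## 1. Image primitives (`ciliaquant.imagecore`)

**Containers.** `ImageStack` holds voxels as `(C, Z, Y, X)` float arrays with
a `Calibration` (µm per pixel in x/y, z-step) and 8/16-bit nominal depth.
Physical→pixel conversion rounds half-up: `um_to_px(v, psz) =
floor(v/psz + 0.5)`.

**Smoothing** is a 3×3 mean with edge truncation (the kernel shrinks at
borders rather than padding), computed as a ratio of box-filtered sums and
counts.

**Rolling-ball background subtraction** estimates the background as a
grayscale opening with a ball structuring element of the given radius
(erosion then dilation with the ball's height profile) and subtracts it;
by construction the background never exceeds the image, so the result is
non-negative. For radii above 16 px the image is min-pooled by
`shrink = max(1, radius // 16)` before the opening and the background is
re-expanded by interpolation — the standard acceleration; a unit test checks
that a point feature on a smooth ramp survives the accelerated path at full
height.

**Auto-thresholding** reduces the image to a 256-bin histogram. 8-bit images
use the identity mapping; other dtypes are linearly rescaled from
`[min, max]` to bins 0–255, and the reported `threshold_value` is mapped back
to the original scale as the selected bin's upper edge,
`lo + (t+1)(hi−lo)/256`. Three criteria are implemented exactly as published
and verified against exhaustive plain-loop scans:

- **Yen** — maximize the maximum-correlation criterion over all thresholds
  with both classes non-empty; ties resolve to the first maximum. The scan is
  restricted to the occupied bin range.
- **Shanbhag** — minimize the absolute difference of fuzzy background/object
  entropies. Note: this criterion is a *zero-crossing selector*; on
  histograms with a narrow background mode plus a sparse bright tail
  (exactly what a background-subtracted cilium projection produces) several
  crossings can differ by ~1e-5, so the selected threshold flips chaotically
  with noise. This instability is inherent to the algorithm, not to this
  implementation (which matches the reference), and is why the recovery
  demonstrations use the Yen-based pipeline variant (§3).
- **MinError(I)** — the iterated Kittler–Illingworth Gaussian-mixture fit,
  started from the histogram mean, using natural logarithms. If the fit
  degenerates (zero class variance, negative discriminant, or
  non-convergence) the method falls back to the histogram-mean threshold and
  attaches a warning to the returned mask.

Constant images raise `DegenerateImageError` rather than returning an
arbitrary threshold.

**Particle analysis** labels 8-connected components and reports area,
perimeter, circularity, centroid `(x, y)`, and an edge-touch flag, with
minimum-size, circularity-window, and exclude-edges filters. The perimeter is
the classical boundary chain-code length (unit steps for axis moves, √2 for
diagonal moves; a single pixel has perimeter 4); circularity `4πA/P²` is
capped at 1. **Watershed separation** splits touching convex blobs via the
distance-transform watershed before particle analysis (used for nuclei).

**Reslicing** maps a `(Z, Y, X)` volume to side views by
`out[y, r, x] = in[Z−1−r, y, x]` (apical side up); it requires isotropic
calibration (`z_step == pixel_size_xy`) and raises `AnisotropyError`
otherwise, since side-view distances are read in µm.

## 2. Synthetic data (`ciliaquant.synth`)

`generate_monolayer` renders a jittered square grid of cells (default 10×10,
10 µm cells, 0.28 µm isotropic voxels) into six channels — nuclei, actin,
γ-tubulin (basal bodies), cilium marker, vesicles, and a generic punctate
marker — then applies a Gaussian PSF and a camera model
`Poisson(signal·scale)/scale + background + N(0, read_sd)`. Ground truth
records every cell center, basal-body position, cilium length, vesicle, and
punctum.

Model elements, each chosen to make a pipeline's true value computable:

| element | model | true statistic |
|---|---|---|
| actin cortex | 1 µm slab at the apical surface; junction ridges below it | — |
| clearing | multiplicative dip: intensity ×(1−d) within `clearing_radius` of the basal body | clearing ratio = analytic window mean |
| cilia | uniform-density rods, length U(2,5) µm, tilt 15–60° from the z axis | ciliation fraction (exact count) |
| nuclei | ellipsoids, 3 µm lateral radius, at z ≈ 4 µm | nucleus count |
| vesicles | non-overlapping spheres, lognormal radii | equatorial area πr² |
| marker puncta | multinomial split between basal body / vesicle rim / cytosol | compartment labels |

Realism features that proved load-bearing for recovery (all default-on):

- **Cilium tilt (15–60°).** Vertical rods project to near-points in a maximum
  projection; real cilia on fixed monolayers lie at an angle and project as
  short rods.
- **Flux-conserving rod rasterization.** Sub-pixel cylinders are rasterized
  by 3³-supersampled volume-fraction coverage. Binary rasterization aliases:
  after PSF blurring the intensity beats along the rod and single cilia
  fragment into 2–3 particles.
- **Cytoplasmic staining in the cilium channel.** Axoneme markers
  (acetylated/polyglutamylated tubulin) also stain cytoplasmic microtubules.
  Modeled as a smooth per-cell Gaussian haze (lognormal amplitude) plus
  discrete 2–4 µm cytoplasmic filaments; the filaments provide the
  small-scale structure that survives rolling-ball subtraction, as in real
  images.
- **Per-vesicle lognormal brightness (σ_ln = 0.8).** Acidotropic dyes
  accumulate to very different degrees between compartments. With uniform
  amplitudes, the Yen threshold sits at a few percent of the brightest blob
  and measured areas carry a +60–70 % halo bias; with a realistic ~ten-fold
  brightness spread the aggregate bias drops to a few percent (dim-vesicle
  censoring balances bright-vesicle halo). Single fields scatter accordingly;
  recovery statements hold at the technical-replicate-averaged level, which
  is how the real protocol reports them.

Known limits: vesicles below ~0.5 µm radius are sub-resolution at 0.21–0.28
µm pixels, and threshold censoring then dominates the measured mean area —
absolute area recovery is only claimed for resolvable (~1 µm) compartments.
Cells are convex and grid-like; junction geometry is a ridge heuristic, not a
Voronoi tessellation.

`generate_vesicle_field` (single-slice LysoTracker fields with
rejection-sampled non-overlapping disks), `generate_coloc_pair` (two-channel
fields sharing a controlled fraction of objects; expected M1/M2 computed by
pixel counting on the noiseless masks), and `generate_replicate_study`
(tidy condition/bio-rep/tech-rep tables with optional injected outliers)
supply the remaining ground truths.

## 3. Pipelines (`ciliaquant.pipelines`)

All pipelines follow the published recipes:

- **lysotracker_size** — crop ROI → smooth → maximum projection →
  rolling-ball r = 20 px → Yen threshold → particles ≥ 3 px with circularity
  0.50–1.00, edge particles excluded → mean area in µm². Degenerate
  (constant) ROIs are skipped with a flag, not silently zero.
- **actin_clearing** — 8×5 µm side-view ROI centered on the basal body;
  columns averaged vertically; profile normalized to mean 1; ratio = mean
  over |x| ≤ 0.3 µm divided by mean over 2 µm ≤ |x| ≤ 4 µm. Windows are
  inclusive with a 1e-9 µm tolerance so exact-boundary pixels behave
  identically across platforms. A uniform profile yields exactly 1.0.
- **percent_ciliation** — cilia: maximum projection → rolling-ball r = 100 →
  threshold → particle count; nuclei: maximum projection → smooth →
  rolling-ball r = 100 → MinError → watershed → particles ≥ 150 px. Two
  published variants: `mdck` (Shanbhag, ≥ 2 px) and `rpe1` (Yen, ≥ 5 px).
  Because of the Shanbhag instability described in §1, quantitative recovery
  is demonstrated with the `rpe1` variant; `mdck` is implemented exactly as
  specified and its components are unit-tested. A `manual_nuclei_override`
  supports hand counts; zero nuclei raises `UndefinedStatisticError`.
- **basal_body_enrichment** — side-view slice → rolling-ball r = 75 → Yen →
  positive-pixel density in a 3×2 µm box centered laterally on the basal
  body (box top at the basal-body row) divided by density in a user polygon
  over the cytosol. Cells whose cytosol is > 99 % or < 0.5 % positive are
  excluded as uninformative. If all signal lies in the box, the fold equals
  A_cytosol/A_bb exactly.
- **manders_overlap** — rolling-ball r = 100 on the chosen slice, optional
  30×30 µm crop, Yen per channel, M1 = |A∩B|/|A|, M2 = |A∩B|/|B|. Empty
  channels yield `None` for the undefined coefficient plus a flag.

## 4. Statistics (`ciliaquant.stats`)

- **Replicate averaging** — technical replicates are averaged within each
  biological replicate before any testing.
- **ROUT outlier exclusion** (one-sample specialization) — robust center =
  median; robust scale (RSDR) = 68.27th percentile of absolute residuals ×
  N/(N−1); residual t statistics with N−1 df; Benjamini–Hochberg step-up at
  FDR level Q (default 0.02). Fewer than 3 values: nothing is excluded.
  Monte-Carlo calibration: clean-data exclusion rate ≈ Q; the textbook
  {5,5,5,5,5,50} case flags exactly the 50.
- **Welch ANOVA** — the heteroscedastic F\* with its companion
  Brown–Forsythe statistic. Two-group F\* equals the squared Welch t exactly;
  null rejection rate is 0.05 ± 0.01 at 10,000 Monte-Carlo reps under
  unequal variances.
- **Dunnett's T3** — Welch-type t per pair with Welch–Satterthwaite df;
  familywise adjustment through the studentized maximum modulus (SMM)
  distribution with family size = number of comparisons. The SMM CDF is
  evaluated as E[(2Φ(xW)−1)^m] over W = χ_df/√df by 200-node Gauss–Legendre
  quadrature on [ppf(1e-12), isf(1e-12)] of W (absolute error ≪ 1e-6);
  `p_adj = max(p_adj, p_unadj)` guards quadrature round-off at m = 1.
  Measured familywise error ≤ 0.06 under a 4-group null at α = 0.05.
- **one_sample_t**, **densitometry_normalize** — standard; densitometry is
  (target/loading) normalized to the WT lane's own ratio.

## 5. IO and determinism

Stacks are written as OME-TIFF (`CZYX`) with physical calibration and channel
names. The OME `UUID` is derived from the SHA-256 of the voxel data
(`uuid5`), so identical stacks are byte-identical files. Result CSVs and JSON
manifests contain no timestamps; a rerun of
`simulate → quantify → stats` with the same seed reproduces every CSV
byte-for-byte. Config files are YAML with strict key checking; per-pipeline
parameters are merged over protocol defaults, and the manifest records a
SHA-256 content hash of the effective configuration.
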