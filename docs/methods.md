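# Methods

spheroquant emulates and analyzes an automated high-content screening (HCS)
workflow for micropatterned-plate spheroids: a low-magnification prescan
that finds spheroids in 2D and selects them for re-imaging, followed by
high-magnification 3D confocal stacks that are segmented down to single
organelles. Because no real image data ship with the package, every stage
is validated against a synthetic phantom generator whose ground truth is
known exactly. This note records the models, the parameters that matter,
and the numerical choices — including where the design was genuinely open.

## The phantom model

A spheroid phantom is an ellipsoidal cell assembly rasterized onto an
anisotropic voxel grid (defaults: 1 µm z steps, 0.3 µm in xy — 63x-class
water-immersion sampling with a coarse z screen step), with:

- **Geometry.** Half axes (35, 35, 17.5) µm: height half the width, the
  flattened shape micropatterned spheroids adopt. Full ellipsoids (not
  caps): the closed form keeps placement and measurement oracles exact.
  Solid interior — no lumen or necrotic core is modelled.
- **Cells.** `n_cells` drawn uniformly from 80–120 per spheroid. Nucleus
  centers are placed by minimum-separation rejection sampling (separation
  1.8 nuclear radii — nuclei in a packed assembly touch and deform, and a
  hard 2r separation is geometrically infeasible at 120 nuclei). Cell
  regions are the nearest-nucleus partition under anisotropic Euclidean
  distance, clipped to the ellipsoid. Nucleus radius defaults to 3.5 µm.
- **Organelles**, per cell:
  - *Golgi*: 125 µm³ total (6% lognormal-like jitter) split over 5–10
    fragments of comparable size, hugging the nuclear surface on one side
    (a per-cell "pole"). Fragments keep ≥ 0.8 µm gaps: the emulated assay
    counts *distinct* fragments at light-microscope resolution, so the
    truth must be resolvable by the rendered optics.
  - *Early endosomes*: 120 µm³ total in **315** equal puncta dispersed
    uniformly through the cytoplasm at ≥ 1 µm separation. The count is not
    a free dial: with total volume V and total measured surface A fixed by
    the study conditions (120 µm³, 800 µm²), equal spheres force
    n = (A / ((36π)^{1/3} V^{2/3}))³ ≈ 315.
  - *Lysosomes*: 30 µm³ in ~20 puncta clustered within 3 µm of a
    perinuclear site — the compact, juxtanuclear distribution that makes
    individual lysosomes hard to count.
  - *EGFP marker* (optional): cytosolic fill, Rab5A-like puncta, or a
    Rab6A-like Golgi marker. The compact Rab6A state is a single bright
    core (2.5 µm³) at the Golgi pole; its small XY footprint is what makes
    the drug-induced footprint change so large (below).
- **Drug phenotypes** are spec transformations applied before rasterization.
  Brefeldin A: fragment count ×25, total volume ×0.85, fragments scattered
  (≥ 1.5 µm apart — "distinct punctate structures"); the Rab6A channel is
  re-rendered as a reticular web of random chords through the cytoplasm,
  dilated to roughly PSF-radius tubes. Nocodazole: ×3 fragments, volume
  ×0.90, milder dispersal of Rab6A.

Rasterization keeps sub-voxel sphere centers, which makes voxelized volumes
unbiased (the expected lattice-point count of a randomly placed body equals
its volume over the voxel volume). A punctum whose extent straddles no
voxel center — possible for sub-voxel bodies on the 1 µm z grid — is
floored to the voxel containing its center, so every drawn object
materializes in the label truth. Per-cell truth volumes are computed *from
the labels*, so conservation (truth = voxel count × voxel volume) holds
exactly by construction.

## The imaging model

Per channel: anisotropic Gaussian PSF blur (σ_xy = 0.13 µm, σ_z = 0.5 µm —
63x/1.15 NA-class), multiplication by a photon scale (300 counts per unit
intensity), Poisson shot noise, Gaussian read noise (σ = 3), a constant
background offset (40 counts), and quantization to unsigned 16-bit. The
nuclei channel carries a 20% residual stain in the cytoplasm — that
residue is what the cytoplasm segmentation exploits. All randomness flows
from a single integer seed through independent, spawned substreams, so
identical specs render bit-identically.

The plate-level generator mirrors the micropatterned well: a square
lattice at 300 µm pitch (45 µm adhesive discs), each site independently
occupied with probability 0.7 (the observed 60–80% spheroid formation
rate), occupied sites carrying a disc of diameter N(70, 5²) µm. Occupied
counts are therefore exactly binomial across seeds — a property the tests
check by χ² goodness of fit.

## The analysis chain

All thresholds are data-derived (no fixed intensity values), all distances
respect voxel anisotropy, 3D connectivity is 26-neighbor, and watershed
ties resolve by raster order, so the chain is deterministic given its
input.

1. **Spheroid region**: Gaussian smooth (σ 3 µm) → threshold → 3D hole
   fill → drop components < 10⁴ µm³. The default 63x profile takes the
   *lowest of two three-class Otsu thresholds*: the stack histogram is
   trimodal (background / dim nuclei-free rim / bright interior), and a
   two-class Otsu lands inside the rim, eroding ~15% of the true volume. A
   contrast guard (foreground-background difference ≥ 2 background SD on
   the raw channel) keeps structure-free stacks empty.
2. **Nuclei**: smooth (σ 0.5 µm) → Otsu within the spheroid → anisotropic
   Euclidean distance transform → h-maxima seeds (h = 0.5 µm) → seeded
   watershed → nuclear volume window 65–1500 µm³. The two sub-micron
   choices matter: σ = 1 µm smoothing dilates nuclear masks by ~30% and
   fuses touching nuclei, and h = 1 µm merges the seeds of nuclei that
   touch (their distance-transform saddle sits ~1.5 µm below peaks).
3. **Cytoplasm and cells**: cytoplasm = spheroid voxels whose smoothed
   nuclei-channel intensity is ≥ 8% of the median intranuclear intensity,
   minus nuclei; cells = seeded watershed on distance-from-nucleus,
   restricted to the spheroid; each cell is its nucleus plus assigned
   cytoplasm (a true partition — per-cell cytoplasm volumes sum exactly).
4. **EGFP gating**: per-cell mean EGFP against
   max(background mean + 3σ, Otsu over per-cell means). The pipeline
   default is `parental` (keep all): phantom stable lines express in every
   cell, mirroring a uniform population name; gating mode is exercised by
   tests with mixed-expression phantoms.
5. **Organelles**, two routes:
   - *Gaussian route* (Golgi-class): smooth → Otsu over cell-region
     voxels → components ≥ a minimum volume → majority-cell assignment.
     Touching structures are split by a seeded watershed at intensity
     saddles (h-maxima at 8% of the threshold). The 63x profile smooths at
     σ = 0.2 µm — the rendered PSF already band-limits the image, and
     stronger smoothing fuses sub-micron drug-induced fragments along the
     coarse z axis — and keeps pieces down to 0.1 µm³ so watershed halves
     of ~0.5 µm³ fragments are not discarded.
   - *Spot-bright route* (endosome/lysosome-class): the scale-normalized
     Hessian spot response (σ = 0.35 µm in the 63x profile, matched to the
     PSF-blurred punctum width), thresholded at median + 6·MAD over cell
     voxels. On densely punctate tissue this rule degenerates (the spot
     map is exactly zero wherever any eigenvalue is non-negative, so the
     median and MAD both vanish); the threshold then falls back to the
     same robust rule on the *positive responses outside the cell region*
     — a pure noise floor — with the 1.4826 MAD-to-σ factor. Spots are
     split by watershed at response saddles (depth scaled to the median
     in-mask response); components within 0.02–30 µm³ are kept.
6. **PLS texture maps** from the γ-normalized (σ²) Gaussian Hessian with
   eigenvalues λ1 ≤ λ2 ≤ λ3, m_i = (−λ_i)₊, p_i = (λ_i)₊:

       spot_bright  = σ²·(m1·m2·m3)^{1/3}
       plane_bright = σ²·m1·(1 − |λ2|/|λ1|)₊·(1 − |λ3|/|λ1|)₊   (λ1 < 0)
       line_bright  = σ²·(m1·m2)^{1/2}·(1 − |λ3|/|λ2|)₊          (λ2 < 0)
       saddle       = σ²·(m1·p3)^{1/2}

   These are rotation invariant, vanish on constants, are offset invariant
   and scale linearly with contrast. Eigenvalues come from a vectorized
   trigonometric closed form (checked against LAPACK in the tests). Two
   discrete-kernel subtleties matter: derivative filters use 6σ support
   (at 4σ the sampled second-derivative kernel leaves a ~10⁻⁴·intensity
   bias on flat regions), and even-order kernels have their DC response
   projected out exactly — below one voxel of σ the sampled kernel's sum
   reaches order one, which would otherwise couple the local intensity
   level into the curvature maps. Cell-level
   texture features (mean plane_bright and saddle over the cytoplasm) are
   divided by the cell's mean EGFP intensity, making them gain invariant.
7. **Morphometrics**: volume = voxel count × voxel volume (exact on the
   grid). Surface area = triangle-mesh area of the 0.5-isosurface
   (marching cubes, anisotropic spacing); for bodies ≥ 16 voxels across in
   every axis the binary mask is mollified with a one-voxel Gaussian first
   — the raw staircase surface carries a ~8% area excess that does *not*
   shrink with voxel size, while the mollified level set converges;
   smaller bodies (puncta) are meshed directly since mollification would
   erase them. Sphericity is Wadell's Ψ = π^{1/3}(6V)^{2/3}/A, unclipped.
   Two width conventions coexist deliberately: the 2D prescan width is the
   minimum Feret (caliper) diameter — a disc's diameter — while the 3D
   spheroid width is the maximum XY Feret of the projection, the
   denominator of the height/width aspect ratio. Per-cell organelle
   surface areas sum per-fragment mesh areas; footprint area counts the
   distinct XY pixel columns holding at least one of the cell's organelle
   voxels, on the raw (unsmoothed) fragment mask.
8. **Statistics**: unpaired two-sample Wilcoxon rank-sum (exact p by
   enumeration for min(n,m) ≤ 8 without ties, else the tie- and
   continuity-corrected normal approximation); one-way ANOVA with Tukey
   HSD (studentized range); one-sample Kolmogorov–Smirnov normality check
   with estimated parameters, whose p-value comes from a seeded
   Lilliefors Monte-Carlo null (default 2000 resamples) since the textbook
   KS null is invalid with estimated mean and SD. Per-cell comparisons
   pool cells across spheroids (matching per-cell n's in screening
   practice); this ignores spheroid-level nesting, a deliberate
   pseudo-replication caveat. No multiple-testing correction is applied
   beyond Tukey's.

## What passing tests do and do not show

The phantoms share the real data's geometry, intensity statistics
(Poisson + read noise, residual stain, diffuse antibody background) and
the anisotropic sampling of a screening confocal. They do not model
depth-dependent light loss, spherical aberration, chromatic offsets,
cell-to-cell intensity heterogeneity, or biological irregularity of
organelle shape (all organelles are spheres or tubes). End-to-end recovery
on phantoms therefore demonstrates that the chain is *internally
consistent and unbiased under its own forward model* — not that it would
reproduce any particular laboratory's absolute numbers.

Two quantitative limits of the emulation are worth knowing:

- **Fragment-count fold change under brefeldin A.** The generated truth
  fold is ~23 (×25 fragments, minus jitter), but at ~187 fragments per
  ~700 µm³ of cytoplasm a large minority of nearest-neighbour pairs are
  separated mainly along z by less than the axial resolution (σ_z 0.5 µm
  on a 1 µm grid). No threshold or watershed can count such pairs apart,
  so the measured fold saturates around 16–18 — consistent with a ">20×"
  observation only at its stated tolerance.
- **Endosome surface area.** The analytic design carries 800 µm² per cell,
  but voxelizing 0.45 µm-radius puncta onto a 1 µm z grid leaves only
  ~620 µm² of mesh area in the *truth labels themselves* (sub-voxel bodies
  lose surface to the grid, and marching cubes trims corners of few-voxel
  masks), and z-resolution merging of ~1 µm-spaced puncta caps faithful
  measurement at 80–90% of that. Reported medians therefore sit around
  500–550 µm², ~35% below the analytic design value — a property of
  anisotropic sampling at a 1 µm z step, not of the segmentation. The
  corresponding acceptance check is expected to fail and is kept anyway,
  as an honest record of this limit.

## Problem sizes

Default end-to-end runs use 20 phantoms per assay arm (~2000 cells per
arm), the full-scale acceptance suite uses 10 phantom seeds for
segmentation recovery, and statistical calibrations use 1000 null
simulations (200 for the Monte-Carlo KS). Single phantoms at the default
grid (44×256×256 voxels, 4 channels) build, render and analyze in well
under a minute on one CPU core.
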