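# Methods

## The measurement

mt-roGFP is a redox-sensitive GFP targeted to the mitochondrial matrix.
Its two excitation peaks respond oppositely to oxidation of the
glutathione pool, so the ratio of emission under 800 nm excitation to
emission under 900 nm excitation (Ratio 800/900) is a concentration- and
path-length-independent readout of matrix redox state; an increase means
oxidation.  In vivo the dynamic range is pinned by saturating topical
application of a reductant (DTT, fully reduced end) and an oxidant (DTDP,
fully oxidised end), which is also how the pseudocolor calibration range
is chosen.

The analysis chain mirrors an intravital two-photon experiment: acquire a
two-channel z-stack, segment individual mitochondria, compute one ratio
per mitochondrion, aggregate per field of view (z-stack) and per animal,
and compare groups or timepoints.

## Forward model (synthetic data)

The generator exists so that every stage has an oracle.  One field is a
127 µm × 127 µm × (n_slices × 2 µm) volume sampled at 512 × 512 px
(pitch 127/512 ≈ 0.248 µm).  Mitochondria are placed per z-slice:
tubular objects 1–4 µm long and ~0.75 µm wide in neurites, round ~1.1 µm
objects clustered inside disc-shaped (10 µm) soma regions.  Placement
rejects overlaps with a 2.5 µm clearance margin so connected-component
counts are unambiguous; irrecoverable over-packing raises an error naming
the realized count, minor shortfalls warn.

Each object carries a true ratio R.  Channel expectations per object
voxel are

    E[ch800] = B·R/(1+R) + b800      E[ch900] = B/(1+R) + b900

with photon budget B = 400 and backgrounds b = 20 photons/voxel by
default.  The R/(1+R) ↔ 1/(1+R) split makes total object brightness
independent of R, so segmentation on the summed image carries no redox
bias and the background-corrected sum ratio equals R exactly without
noise.  A lateral Gaussian PSF (σ = 0.3 µm; the 2 µm z-step undersamples
the axial PSF, so no axial blur) is applied to the noise-free expectation,
then per-voxel Poisson noise — optics first, shot noise last.  Plaques are
spheres rendered into a third channel (peak 300 photons/voxel over a
5-photon floor).

True ratios are drawn Normal(ratio_mean, ratio_sd) truncated positive
(defaults 1.06 and 0.15: the published basal group mean, and a spread
consistent with the published per-volume histograms).  In gradient mode
the ratio is instead the deterministic plaque-proximity law
R(d) = R_far + (R_near − R_far)·exp(−d/λ) evaluated at the object's true
distance d to the nearest plaque edge (defaults R_near 1.6, R_far 1.0,
λ = 20 µm).  Paired acquisitions reuse the same scene with every true
ratio multiplied by a fold and independent noise draws.

Seeds: one master seed; every per-stack and per-stage seed is derived by
fixed integer arithmetic (`derive_seed`), so cohorts and full runs are
bit-reproducible.

What the generator does **not** emulate — and what passing recovery tests
therefore cannot certify on real data: vasculature and dye channels
bleeding through, depth-dependent attenuation and scattering, motion,
photobleaching, spatially varying background, and non-spherical plaque
morphology.  Real-data use should validate background estimation and
plaque masks visually.

## Pipeline stages and numerical choices

**Background.**  Per channel and slice, the p-th percentile (default
p = 5) of a Gaussian-smoothed copy of the slice (σ = 2 µm).  The smoothing
matters: on the raw image the 5th percentile reads the lower tail of shot
noise (≈ 1.6 SD below the true background), which propagates into a
ratio-toward-1 bias of every object; after 2 µm smoothing the residual
bias is ≈ 0.3 photon.  An ROI method (mean inside a user mask) is
available when a background region is known.

**Segmentation.**  Detection image = clip(ch800c + ch900c, 0) where the c
subscript denotes background subtraction.  Threshold = local Gaussian
mean (window 4 µm, σ = window/4) + offset × noise SD, with the noise SD
estimated per slice as 1.4826 × MAD of the unclipped detection image
(zero for noise-free input, which makes noise-free segmentation exact).
The offset defaults to 2 SDs: simulations at the default photon budget
show that 1 SD admits thousands of ≥ 8 px noise clusters per stack while
2 SDs admits essentially none, and object peaks sit ~30 SDs above
threshold either way.  Components are 2-D 8-connected per slice by
default (2 µm z-steps undersample ~1 µm objects; 3-D 26-connectivity is a
config switch), ordered by (slice, raster) for determinism, and kept if
their pixel count lies in [8, 1500] (≈ 0.5–92 µm² at default pitch).
Objects whose corrected 900-nm sum is nonpositive are excluded and
logged, not fatal.

**Ratios.**  Per-object ratio is the sum ratio with per-voxel clipping at
zero after background subtraction (prevents negative sums; also the
source of a small toward-1 bias in dim halo voxels, measured < 0.5% at
default SNR).  Summing pools photons, so the estimator is much less noisy
than the mean of per-pixel ratios and is exactly invariant to common
rescaling of both channels.  Pixelwise ratio images mark voxels invalid
where corrected ch900 falls below a floor (default 2·√b900), since
near-zero denominators produce unbounded ratios.

**Compartments.**  A supplied soma mask is authoritative.  The heuristic
otherwise: threshold the detection image at 3 noise SDs, close gaps with
a 2 µm disc so clustered somatic mitochondria fuse, and call blobs larger
than 50 µm² soma regions.  The 2 µm closing radius is below the 2.5 µm
inter-object clearance, so isolated neurites do not fuse; agreement with
generator truth exceeds 90% at default SNR.

**Distances.**  Distance from an object centroid (continuous physical
point) to the nearest *boundary* voxel centre of the plaque mask, with
anisotropic spacing, via a KD-tree; centroids inside the mask score 0 and
are flagged, not excluded.  Voxel-centre geometry keeps the operation
exactly checkable against a brute-force oracle; the cost is a bias of at
most half a voxel.  An empty mask yields "not applicable", never 0 or ∞.

**Spatial profile.**  Records within 70 µm are binned in 10 µm bins (both
configurable).  The headline Pearson r correlates per-bin mean distance
with per-bin mean ratio — mean distance rather than bin centre so that
exactly linear data gives exactly |r| = 1 — with the per-record r
reported alongside, and per-bin SEM and an optional
fraction-above-threshold summary emitted for both interpretations of an
occupancy-style profile.

**Rendering.**  t = clip((R − R_min)/(R_max − R_min), 0, 1); hue runs
linearly 240° (blue, reduced) → 0° (red, oxidised), saturation 1, and the
HSV Value channel carries the summed-channel intensity normalised by its
99.5th percentile.  Invalid-ratio voxels render gray at their intensity.
Default calibration [1.0, 1.6] brackets the published basal (1.06) and
oxidised (1.55) in vivo means.  Rendering is pure visualisation.

**Statistics.**  Two groups: Mann–Whitney (exact by ranking enumeration
when n₁+n₂ ≤ 12 without ties, tie-corrected normal approximation with
continuity correction otherwise) or paired t (degenerate constant
differences are reported as such).  Three or more groups: Kruskal–Wallis
(tie-corrected) with Dunn's mean-rank z post-hoc, Bonferroni-adjusted
across pairs by default (the adjustment is configurable because the
original analyses ran in commercial software whose default is unstated).
Pearson correlation with r², t-distributed p on n−2 df.
Benjamini–Hochberg step-up adjustment with a 0.25 FDR selection threshold
as the display-rule default.  Aggregation is unweighted at each level of
the hierarchy (objects → stack means → subject means), and results are
labelled with the level used.

## Validation suite problem sizes

The validation tests run the same machinery as the reproduction script at
desk scale, chosen so the whole suite stays interactive: ratio-recovery
cohorts of 8 and 6 stacks (10 slices) at the 2% tolerance; paired
recovery with 5 and 4 pairs (10 slices) at 3 SEM; spatial sign recovery
over 100 gradient and 100 null fields of 320 px × 5 slices; type-I
calibration with 2000 null simulations per test (n = 30 per group for
Mann–Whitney and Pearson, 20 pairs for the paired t, 3 × 15 for
Kruskal–Wallis and Dunn).  `scripts/acceptance.py` uses the full cohort
sizes (30/20 stacks at 20 slices; 24/20 pairs at 12 slices).

## Known limitations

- The per-object estimator is nearly unbiased at the default photon
  budget but acquires a toward-1 bias at very low SNR (clipping of dim
  voxels); the paired ΔR/R₀ largely cancels it.
- Per-slice 2-D segmentation counts a mitochondrion spanning z-slices
  once per slice; PSF blur can merge tightly clustered somatic
  mitochondria into one object.  Neither affects ratio estimates (any
  footprint drawn from one redox environment yields that environment's
  ratio), but object counts are "resolved objects", not organelles.
- Compartment assignment is a heuristic unless soma masks are supplied.
- Plaque recovery from the plaque channel is threshold-based
  (Otsu + hole filling); manually curated masks remain authoritative.
- No absolute redox-potential calibration (Nernst conversion): ratios are
  relative, as reported.
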