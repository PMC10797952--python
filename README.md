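# mitoredox

Quantitative analysis of **mitochondrial oxidative stress imaged in vivo**
with a ratiometric, mitochondria-targeted redox sensor (mt-roGFP).  The
sensor's two excitation peaks shift with the glutathione redox couple, so
the ratio of fluorescence excited at 800 nm over 900 nm — **Ratio
800/900** — reports the redox state of the mitochondrial matrix: higher
ratio, more oxidised.

The package is written for microscopists and analysts working with
two-photon z-stacks of neuronal mitochondria, in particular in amyloid-β
(Aβ) mouse models of Alzheimer's disease.  It provides:

- **Segmentation** — adaptive thresholding of the summed-channel image
  (local Gaussian mean + noise-scaled offset), connected components with a
  size constraint, soma/neurite compartment assignment;
- **Ratiometry** — per-object sum ratios
  `R = Σ(ch800 − bg₈₀₀)⁺ / Σ(ch900 − bg₉₀₀)⁺`, per-pixel ratio images with
  validity masking, per-stack summaries;
- **Paired analysis** — ΔR/R₀ = 100·(R_after − R_basal)/R_basal between
  re-imaged fields, with the ≥ 25% responder rule;
- **Spatial analysis** — centroid-to-plaque-edge distances (anisotropic
  voxels) and the binned ratio-vs-distance Pearson correlation within 70 µm;
- **Rendering** — HSV pseudocolor panels (ratio → hue between the DTT/DTDP
  calibration anchors, summed intensity → Value);
- **Statistics** — Mann–Whitney (exact for small samples), paired t,
  Kruskal–Wallis + Dunn, Pearson, Benjamini–Hochberg FDR;
- **Synthetic data** — a forward model of the acquisition
  (127 µm × 127 µm × 512 × 512 px fields, 2 µm z-steps, Gaussian PSF,
  Poisson photon noise) with per-object ground truth, so every stage of the
  pipeline can be validated against known answers.

The forward model renders an object with true ratio R as
`E[ch800] = B·R/(1+R) + b₈₀₀` and `E[ch900] = B/(1+R) + b₉₀₀` (B = photon
budget), which makes total brightness ratio-independent and the sum-ratio
estimator exactly invertible in the noise-free limit.

## Worked example

`examples/` holds one short script per capability.  The paired ΔR/R₀
analysis (`examples/02_paired_delta.py`) simulates four fields re-imaged
after an oxidising insult that multiplies every true ratio by 1.325 and
recovers the change through the full pipeline:

```
fov0: R_basal 1.011 -> R_after 1.337, dR/R0 +32.29%  responder=True
fov1: R_basal 0.986 -> R_after 1.305, dR/R0 +32.40%  responder=True
fov2: R_basal 1.008 -> R_after 1.337, dR/R0 +32.62%  responder=True
fov3: R_basal 1.000 -> R_after 1.323, dR/R0 +32.29%  responder=True

mean dR/R0 = 32.40% (true change 32.50%)
```

Each line is one field of view: its basal and post-treatment mean ratio,
the relative change, and whether it clears the 25% responder threshold.
The mean across fields recovers the configured +32.5% true change to
within a fraction of a percentage point.

The spatial profile (`examples/03_plaque_distance_profile.py`) simulates a
plaque-proximity redox gradient R(d) = 1.0 + 0.6·e^(−d/20 µm) and recovers
a binned Pearson r of about −0.95 across 10 µm bins within 70 µm of the
plaque edge — oxidation highest at the plaque, decaying to baseline.

A thin CLI mirrors the library (`mitoredox simulate|segment|quantify|
paired|spatial|render|stats|full-run`); see `mitoredox --help`.

## Layout

```
src/mitoredox/     config, synth, stacks, io, segmentation, ratiometry,
                   spatial, rendering, stats, pipeline, validation, cli
tests/             unit + property tests and the validation suite
examples/          one narrative script per capability
docs/methods.md    models, parameters, numerical choices, limitations
```
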