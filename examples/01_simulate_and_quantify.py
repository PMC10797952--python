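"""Simulate one two-channel cortical field and quantify its mitochondria.

Builds a synthetic 127 µm × 127 µm z-stack (100 mitochondria, Poisson
noise), runs background estimation, adaptive segmentation and per-object
sum-ratio quantification, and compares the recovered per-stack mean Ratio
800/900 with the generator's ground truth.
"""

import numpy as np

from mitoredox import (
    GeneratorConfig,
    build_scene,
    quantify_stack,
    render_stack,
    stack_summary,
)

config = GeneratorConfig(ratio_mean=1.06, ratio_sd=0.15, seed=7)
scene = build_scene(config)
stack = render_stack(scene, config)

background, labels, objects = quantify_stack(stack)
summary = stack_summary(objects, "demo")

print(f"ground truth: {scene.n_objects} objects, mean R_true "
      f"{scene.true_ratios.mean():.4f}")
print(f"recovered   : {summary.n_objects} objects, mean Ratio 800/900 "
      f"{summary.mean_ratio:.4f}")
print(f"background  : ch800 {background.bg800.mean():.1f}, "
      f"ch900 {background.bg900.mean():.1f} photons/voxel (true: 20, 20)")
soma = summary.compartment_means.get("soma", float("nan"))
neurite = summary.compartment_means.get("neurite", float("nan"))
print(f"compartments: soma {soma:.3f}, neurite {neurite:.3f}")
print("A recovered mean within a couple of percent of the configured 1.06 "
      "(the basal in vivo group mean) shows the estimator is unbiased at "
      "this photon budget.")
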