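"""Paired before/after imaging of the same fields: ΔR/R0 and responders.

Re-imaging the same cortical volumes after applying an oxidising treatment
multiplies every mitochondrion's true ratio by a common fold.  Here the
fold is 1.325 — a +32.5% true change, the scale reported for Aβ-oligomer-
rich conditioned media — and each stack's ΔR/R0 is recovered through the
full pipeline.  Stacks with ΔR/R0 ≥ 25% count as responders.
"""

import numpy as np

from mitoredox import (
    GeneratorConfig,
    build_scene,
    delta_r,
    generate_paired,
    quantify_stack,
    stack_summary,
)

fold = 1.325
deltas = []
for i in range(4):
    config = GeneratorConfig(ratio_mean=1.0, seed=100 + i, n_slices=10)
    scene = build_scene(config)
    before, after = generate_paired(scene, fold, config)
    summaries = {}
    for name, stk in (("before", before), ("after", after)):
        _, _, objects = quantify_stack(stk, classify=False)
        summaries[name] = stack_summary(objects, stack_id=f"fov{i}")
    pm = delta_r(summaries["before"], summaries["after"])
    deltas.append(pm.delta_pct)
    print(f"fov{i}: R_basal {pm.r_basal:.3f} -> R_after {pm.r_after:.3f}, "
          f"dR/R0 {pm.delta_pct:+.2f}%  responder={pm.responder}")

d = np.array(deltas)
print(f"\nmean dR/R0 = {d.mean():.2f}% (true change {100 * (fold - 1):.2f}%); "
      "every field exceeds the 25% responder rule, as expected for a "
      "uniform oxidising insult.")
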