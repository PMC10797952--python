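"""Ratio vs distance to the nearest amyloid plaque edge.

Simulates a field containing one plaque and a plaque-proximity redox
gradient R(d) = 1.0 + 0.6·exp(−d/20 µm): mitochondria near the plaque edge
are more oxidised.  The pipeline recovers the plaque from its own imaging
channel, measures centroid-to-edge distances, bins them in 10 µm steps
within 70 µm, and reports the binned Pearson correlation.
"""

from mitoredox import GradientModel
from mitoredox.validation import gradient_field_correlation

result = gradient_field_correlation(
    master_seed=5,
    gradient=GradientModel(r_near=1.6, r_far=1.0, lambda_um=20.0),
)

print(result.profile.round(3).to_string(index=False))
print(f"\nbinned Pearson r = {result.r:.3f} (r^2 = {result.r_squared:.3f}, "
      f"p = {result.p_value:.2e}, n = {result.n} mitochondria)")
print(f"per-record r     = {result.r_per_record:.3f}")
print("A strongly negative r reproduces the hallmark spatial signature: "
      "mitochondrial oxidative stress rises toward the plaque edge and "
      "decays to baseline within tens of micrometres.")
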