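"""Derive resistance-factor weights from an expert pairwise comparison
matrix and check the judgements' consistency.

The ten factors are five ecological gradients (elevation E1, slope E2,
relief E3, NDVI E4, distance to water E5) and five disturbance gradients
(land cover A1, distances to three road classes A2.1-A2.3, distance to
settlements A3).
"""

from panlink.ahp import compute_weights, example_expert_matrix

matrix = example_expert_matrix()
wv = compute_weights(matrix)

print("factor weights (sum to 1):")
for label, w in wv.as_dict().items():
    print(f"  {label:<5} {w:.4f}")
print(f"lambda_max = {wv.lambda_max:.6f}  (>= n = {matrix.n} for reciprocal matrices)")
print(f"CI = {wv.ci:.6f}, CR = {wv.cr:.6f}")
print("CR < 0.10, so the pairwise judgements are consistent enough to use"
      if wv.cr < 0.10 else "CR >= 0.10: judgements should be re-elicited")
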