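"""All-vs-all comparison of CCC, Pearson and Spearman on a planted matrix.

Simulates 30 noise features (n = 200) with one planted monotone pair and one
planted quadratic pair, tiers every pair per method (top/bottom 30%), builds
the intersection table and ranks the disagreement pairs (CCC high, another
method low) — the candidates for nonlinear relationships.
"""

from cccoef import FixtureSpec, generate_matrix, run_comparison

planted = [
    ((0, 1), FixtureSpec("monotone", n_samples=200, noise_sd=0.02, seed=101)),
    ((2, 3), FixtureSpec("quadratic", n_samples=200, noise_sd=0.02, seed=102)),
]
matrix, truth = generate_matrix(30, 200, planted, seed=9)
res = run_comparison(matrix.features, seed=9)

print("planted pairs:")
print(truth.to_string(index=False))
print()
nonzero = res.intersections.table.query("count > 0")
print("intersection groups with at least one pair:")
print(nonzero.to_string(index=False))
print()
print("top 5 disagreement pairs (CCC high, Pearson or Spearman low):")
print(res.top_disagreements.head(5).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("The monotone pair lands in the all-high agreement group (every method")
print("sees it); the quadratic pair tops the disagreement list — high CCC with")
print("low linear coefficients is the signature of a nonlinear pattern.")
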