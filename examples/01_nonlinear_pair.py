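"""Detect a nonlinear (quadratic) relationship that Pearson misses.

Builds y = x^2 + noise with x mirrored symmetric about zero, computes the
clustermatch coefficient and the product-moment correlation, and compares
both against a pooled permutation-null threshold.
"""

import numpy as np

from cccoef import FixtureSpec, ccc_pair, generate_pair, numeric_feature, permutation_threshold

x, y, _ = generate_pair(FixtureSpec("quadratic", n_samples=100, seed=17))
result = ccc_pair(x, y)
pearson = float(np.corrcoef(x.values, y.values)[0, 1])

rng = np.random.default_rng(55)
null_features = [numeric_feature(f"g{i}", rng.normal(size=100)) for i in range(20)]
threshold = permutation_threshold(null_features, n_perms=500, q=0.99, seed=56)

print(f"ccc            = {result.value:.4f}  (best partition pair: k_x={result.best_k_x}, k_y={result.best_k_y})")
print(f"|pearson|      = {abs(pearson):.4f}")
print(f"null threshold = {threshold:.4f}  (99th percentile of 500 permuted-pair coefficients)")
print()
print("The clustermatch coefficient sits far above the permutation null while")
print("the product-moment correlation is indistinguishable from noise: the")
print("quadratic dependence is real but invisible to a linear statistic.")
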