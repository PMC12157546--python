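"""Interpret a nonlinear gene pair through sample metadata.

Builds a sex-dimorphic gene (expressed proportionally to a driver in one
group, silent in the other — the chromosome-Y archetype) and correlates it
against categorical and numeric metadata variables with the same coefficient,
exploiting its mixed-type support.
"""

import numpy as np
import pandas as pd

from cccoef import (
    FeatureMatrix,
    MetadataTable,
    categorical_feature,
    gene_metadata_correlation,
    numeric_feature,
)

n = 100
rng = np.random.default_rng(91)
driver = rng.uniform(0.1, 1.0, n)
sex = np.array(["M"] * (n // 2) + ["F"] * (n // 2), dtype=object)
gene = np.where(sex == "M", 2.0 * driver, 0.0)
sample_ids = [f"S{i:04d}" for i in range(n)]

expression = FeatureMatrix(
    [numeric_feature("dimorphic_gene", gene), numeric_feature("noise_gene", rng.normal(size=n))],
    sample_ids,
)
metadata = MetadataTable(
    [categorical_feature("sex", sex), numeric_feature("bmi", rng.normal(27, 4, n))],
    sample_ids,
)
pairs = pd.DataFrame({"feature_i": ["dimorphic_gene"], "feature_j": ["noise_gene"]})

table = gene_metadata_correlation(expression, metadata, pairs)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print("ccc = 1.0 for the dimorphic gene against sex: the gene's two-cluster")
print("quantile partition coincides exactly with the sex labels, so the")
print("categorical variable fully explains the expression pattern. The noise")
print("gene correlates with nothing.")
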