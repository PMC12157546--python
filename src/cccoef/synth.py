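"""Seeded generators for every relationship class the comparison analysis
is built to detect.

Pattern classes (each the analogue of a showcased gene-pair archetype):

``monotone``
    y is a strictly increasing function of x plus Gaussian noise — the case
    every method should flag.
``quadratic``
    y = x^2 + noise with x mirrored exactly symmetric about 0, so the sample
    third moment (and hence the product-moment correlation with y) vanishes
    at zero noise while the dependence is perfect — nonlinear signal that
    Pearson/Spearman miss by construction.
``two_group_linear``
    Sex-dimorphic archetype: group A follows y = slope*x + noise, group B is
    constant at zero (plus noise) — a linear relationship present in one
    subgroup only.
``simpson_reversal``
    Mortality-cohort archetype: both subgroups share a positive within-group
    slope, but the group intercept offset is solved in closed form from the
    realized draws so the pooled least-squares slope is guaranteed negative —
    the pooled linear methods detect the *wrong* pattern.
``masked_subset``
    One subgroup is linear, the other is independent noise that masks it.
``null``
    x and y independent.

All generators are pure functions of their :class:`FixtureSpec`, so
regenerating with the same spec yields identical data.  Noise is additive
Gaussian (``noise_sd``); signals are on unit scale, so the default
noise_sd = 0.05 corresponds to the visually tight exemplar patterns, not to
realistic RNA-seq count noise (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import FeatureMatrix, MetadataTable
from .partitioning import FeatureVector, categorical_feature, numeric_feature

PATTERNS = ("monotone", "quadratic", "two_group_linear", "simpson_reversal", "masked_subset", "null")

DEFAULT_NOISE_SD = 0.05


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic feature pair."""

    pattern: str
    n_samples: int = 100
    noise_sd: float = DEFAULT_NOISE_SD
    group_fraction: float = 0.5
    slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ParameterError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if self.n_samples < 20:
            raise ParameterError(f"n_samples must be >= 20, got {self.n_samples}")
        if not (0.0 < self.group_fraction < 1.0):
            raise ParameterError(f"group_fraction must be in (0, 1), got {self.group_fraction}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


#: presets named after the archetypes they emulate
PRESETS = {
    "sex-dimorphic": FixtureSpec("two_group_linear", n_samples=200, noise_sd=0.0, seed=11),
    "mortality-simpson": FixtureSpec("simpson_reversal", n_samples=200, noise_sd=0.05, seed=12),
    "masked-subset": FixtureSpec("masked_subset", n_samples=200, noise_sd=0.05, seed=13),
}


def _noise(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)


def generate_pair(spec: FixtureSpec):
    """Generate one (x, y) feature pair plus per-sample group labels.

    Returns ``(x, y, groups)`` where groups is an array of 'A'/'B' labels
    (all 'A' for ungrouped patterns).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    groups = np.full(n, "A", dtype=object)

    if spec.pattern == "monotone":
        x = rng.uniform(0.0, 1.0, n)
        y = spec.slope * x + _noise(rng, spec.noise_sd, n)

    elif spec.pattern == "quadratic":
        m = n // 2
        u = rng.uniform(0.0, 1.0, m)
        x = np.concatenate([u, -u] + ([np.zeros(1)] if n % 2 else []))
        perm = rng.permutation(n)
        x = x[perm]
        y = x**2 + _noise(rng, spec.noise_sd, n)

    elif spec.pattern == "two_group_linear":
        m = int(round(n * spec.group_fraction))
        m = min(max(m, 1), n - 1)
        groups[m:] = "B"
        x = rng.uniform(0.05, 1.0, n)
        y = np.where(groups == "A", spec.slope * x, 0.0) + _noise(rng, spec.noise_sd, n)

    elif spec.pattern == "simpson_reversal":
        m = int(round(n * spec.group_fraction))
        m = min(max(m, 2), n - 2)
        groups[m:] = "B"
        dx = 1.5  # horizontal offset between subgroup x-ranges
        x = rng.uniform(0.0, 1.0, n)
        x[m:] += dx
        y = spec.slope * np.where(groups == "A", x, x - dx) + _noise(rng, spec.noise_sd, n)
        # shift group B vertically so the pooled least-squares slope equals
        # -slope exactly on the realized draws (closed form, not sampled-for)
        xc = x - x.mean()
        sxx = float(np.sum(xc * xc))
        sxy0 = float(np.sum(xc * (y - y.mean())))
        t = float(np.sum(xc[m:]))
        offset = (-spec.slope * sxx - sxy0) / t
        y[m:] += offset
        for lo, hi in ((0, m), (m, n)):
            bw = np.polyfit(x[lo:hi], y[lo:hi], 1)[0]
            if bw <= 0:
                raise ParameterError(
                    "simpson_reversal: realized within-group slope non-positive; "
                    "noise_sd too large for this slope/sample size"
                )

    elif spec.pattern == "masked_subset":
        m = int(round(n * spec.group_fraction))
        m = min(max(m, 1), n - 1)
        groups[m:] = "B"
        x = rng.uniform(0.0, 1.0, n)
        y = np.empty(n)
        y[:m] = spec.slope * x[:m] + _noise(rng, spec.noise_sd, m)
        y[m:] = rng.uniform(0.0, spec.slope, n - m) + _noise(rng, spec.noise_sd, n - m)

    else:  # null
        x = rng.normal(0.0, 1.0, n)
        y = rng.normal(0.0, 1.0, n)

    xf = numeric_feature(f"{spec.pattern}_x", x)
    yf = numeric_feature(f"{spec.pattern}_y", y)
    return xf, yf, groups


def generate_matrix(
    n_features: int,
    n_samples: int,
    planted: Sequence[tuple] = (),
    seed: int = 0,
):
    """Feature matrix of independent Gaussian noise with planted pattern pairs.

    ``planted`` is a sequence of ``((i, j), FixtureSpec)`` entries; the rows at
    positions i and j are replaced by the spec's generated pair.  Planted
    feature indices must be distinct across all entries.  Returns
    ``(FeatureMatrix, truth)`` where truth records every planted pair and its
    pattern.
    """
    if n_features < 2:
        raise ParameterError("need at least 2 features")
    used: set[int] = set()
    for (i, j), fspec in planted:
        if i == j or not (0 <= i < n_features) or not (0 <= j < n_features):
            raise ParameterError(f"planted pair ({i}, {j}) out of range or degenerate")
        if i in used or j in used:
            raise ParameterError(f"planted feature index reused in pair ({i}, {j})")
        if fspec.n_samples != n_samples:
            raise ParameterError(
                f"planted spec n_samples={fspec.n_samples} != matrix n_samples={n_samples}"
            )
        used.update((i, j))
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, 1.0, (n_features, n_samples))
    ids = [f"gene_{i:04d}" for i in range(n_features)]
    truth_rows = []
    for (i, j), fspec in planted:
        xf, yf, _ = generate_pair(fspec)
        data[i] = xf.values
        data[j] = yf.values
        truth_rows.append({"feature_i": ids[min(i, j)], "feature_j": ids[max(i, j)], "pattern": fspec.pattern})
    features = [numeric_feature(ids[i], data[i]) for i in range(n_features)]
    sample_ids = [f"S{s:04d}" for s in range(n_samples)]
    truth = pd.DataFrame(truth_rows, columns=["feature_i", "feature_j", "pattern"])
    return FeatureMatrix(features, sample_ids), truth


def generate_metadata(n_samples: int, seed: int = 0, missing_fraction: float = 0.05) -> MetadataTable:
    """Sample metadata table: two binary categoricals (sex and cohort
    analogues) and two numerics (BMI and age analogues), with a little
    missingness in the numeric columns."""
    if n_samples < 2:
        raise ParameterError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{s:04d}" for s in range(n_samples)]
    sex = np.where(rng.random(n_samples) < 0.5, "M", "F").astype(object)
    cohort = np.where(rng.random(n_samples) < 0.6, "Postmortem", "OrganDonor").astype(object)
    bmi = rng.normal(27.0, 4.0, n_samples)
    age = rng.integers(20, 71, n_samples).astype(float)
    if missing_fraction > 0:
        bmi[rng.random(n_samples) < missing_fraction] = np.nan
        age[rng.random(n_samples) < missing_fraction] = np.nan
    variables = [
        categorical_feature("sex", sex),
        categorical_feature("cohort", cohort),
        numeric_feature("bmi", bmi),
        numeric_feature("age", age),
    ]
    return MetadataTable(variables, sample_ids)
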