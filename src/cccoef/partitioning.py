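"""Sample partitioning — the first half of the clustermatch coefficient.

Each feature is converted into one or more *partitions* of the samples:

* a numeric feature yields one quantile partition per cluster count ``k``,
  where sample ``i`` gets label ``min(floor(q_i * k), k - 1)`` and ``q_i`` is
  its empirical midrank percentile ``(rank_i - 0.5) / n``.  Equal values share
  a midrank and therefore a label, so ties never straddle a cluster boundary,
  and cluster sizes are as balanced as the ties permit;
* a categorical feature induces exactly one partition: two samples share a
  cluster iff they share a category label.  Category names map to integer
  labels in lexicographic order, which keeps runs reproducible across
  platforms and dict orderings.

Because the quantile partition depends on values only through their ranks, it
is invariant under any strictly increasing transform of a tie-free feature —
the property that makes the downstream coefficient insensitive to monotone
re-expression (log, exp, cube, ...) of either variable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateInputError, ParameterError, ShapeError

NUMERIC = "numeric"
CATEGORICAL = "categorical"

#: tokens treated as missing when building categorical features from text
MISSING_TOKENS = ("", "NA", "NaN", "nan", "None")


@dataclass(frozen=True)
class FeatureVector:
    """One feature's values across samples, numeric or categorical, with an
    explicit missing-value mask (True = missing)."""

    id: str
    values: np.ndarray
    dtype: str
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.dtype not in (NUMERIC, CATEGORICAL):
            raise ParameterError(f"dtype must be '{NUMERIC}' or '{CATEGORICAL}', got {self.dtype!r}")
        values = np.asarray(self.values)
        mask = np.asarray(self.missing_mask, dtype=bool)
        if values.ndim != 1 or mask.ndim != 1 or values.shape[0] != mask.shape[0]:
            raise ShapeError(
                f"feature {self.id!r}: values and missing_mask must be 1-D of equal "
                f"length (got {values.shape} and {mask.shape})"
            )
        if self.dtype == NUMERIC:
            values = values.astype(float, copy=False)
            bad = ~np.isfinite(values) & ~mask
            if bad.any():
                raise ParameterError(
                    f"feature {self.id!r}: non-finite numeric values at positions "
                    f"{np.flatnonzero(bad)[:5].tolist()} not covered by missing_mask"
                )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "missing_mask", mask)

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_nonmissing(self) -> int:
        return int((~self.missing_mask).sum())


def numeric_feature(fid: str, values: Iterable[float]) -> FeatureVector:
    """Build a numeric FeatureVector; NaN/inf entries become missing."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    mask = ~np.isfinite(arr)
    return FeatureVector(fid, arr, NUMERIC, mask)


def categorical_feature(fid: str, labels: Iterable, missing_mask: Iterable | None = None) -> FeatureVector:
    """Build a categorical FeatureVector.

    If ``missing_mask`` is not given, ``None``, float NaN and the textual
    tokens in :data:`MISSING_TOKENS` are treated as missing.
    """
    arr = np.asarray(list(labels), dtype=object)
    if missing_mask is None:
        mask = np.array(
            [
                (v is None)
                or (isinstance(v, float) and np.isnan(v))
                or (isinstance(v, str) and v in MISSING_TOKENS)
                for v in arr
            ],
            dtype=bool,
        )
    else:
        mask = np.asarray(list(missing_mask), dtype=bool)
    arr = np.array([("" if m else str(v)) for v, m in zip(arr, mask)], dtype=object)
    return FeatureVector(fid, arr, CATEGORICAL, mask)


@dataclass(frozen=True)
class Partition:
    """Assignment of samples to clusters.

    ``labels`` take values in ``[0, k-1]``; ``valid`` is True iff at least two
    clusters are non-empty (a single-cluster partition carries no association
    information and is excluded from the coefficient's maximisation).
    """

    labels: np.ndarray
    k: int
    n_effective_clusters: int
    valid: bool

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int32)
        if labels.size and (labels.min() < 0 or labels.max() >= self.k):
            raise ParameterError(f"labels out of range [0, {self.k - 1}]")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return int(self.labels.shape[0])


@dataclass(frozen=True)
class PartitionSet:
    """All partitions derived from one feature (one per k, or a single
    label-induced partition for categorical features)."""

    feature_id: str
    partitions: tuple

    def __post_init__(self) -> None:
        parts = tuple(self.partitions)
        if not parts:
            raise ParameterError("PartitionSet needs at least one partition")
        lengths = {p.n for p in parts}
        if len(lengths) > 1:
            raise ShapeError(f"partitions of {self.feature_id!r} have differing lengths {sorted(lengths)}")
        object.__setattr__(self, "partitions", parts)

    def __len__(self) -> int:
        return len(self.partitions)

    def __getitem__(self, i: int) -> Partition:
        return self.partitions[i]

    @property
    def n(self) -> int:
        return self.partitions[0].n


def quantile_partition(values: Sequence[float], k: int) -> Partition:
    """Partition numeric values into up to ``k`` clusters by midrank quantiles.

    Labels are monotone non-decreasing in value rank and equal values always
    share a label.  With tie-free input and ``k | n`` the clusters are exactly
    equal-sized; otherwise sizes differ by at most one (ties permitting).
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1:
        raise ShapeError("values must be 1-D")
    if vals.size == 0:
        raise DegenerateInputError("cannot partition an empty vector")
    if not np.all(np.isfinite(vals)):
        raise ParameterError("values must be finite (remove missing first)")
    n = vals.size
    q = (rankdata(vals, method="average") - 0.5) / n
    labels = np.minimum(np.floor(q * k).astype(np.int32), k - 1)
    n_eff = int(np.unique(labels).size)
    return Partition(labels, k, n_eff, n_eff >= 2)


def categorical_partition(labels: Sequence) -> Partition:
    """Partition induced by category labels, mapped to integers in
    lexicographic order of the category names."""
    arr = np.asarray(list(labels), dtype=object)
    if arr.size == 0:
        raise DegenerateInputError("cannot partition an empty label vector")
    names = sorted({str(v) for v in arr})
    index = {name: i for i, name in enumerate(names)}
    coded = np.fromiter((index[str(v)] for v in arr), dtype=np.int32, count=arr.size)
    k = len(names)
    return Partition(coded, k, k, k >= 2)


def precompute_partitions(feature: FeatureVector, k_range: Iterable[int]) -> PartitionSet:
    """Compute every partition of a feature once, over its non-missing samples.

    Numeric features get one partition per ``k`` in ``k_range`` (sorted
    ascending); partitions with ``k`` exceeding the number of non-missing
    samples are flagged invalid.  Categorical features get exactly one
    partition regardless of ``k_range``.
    """
    observed = ~feature.missing_mask
    if feature.dtype == CATEGORICAL:
        vals = feature.values[observed]
        if vals.size == 0:
            raise DegenerateInputError(f"feature {feature.id!r}: all values missing")
        return PartitionSet(feature.id, (categorical_partition(vals),))

    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ParameterError("k_range must be non-empty")
    if ks[0] < 2:
        raise ParameterError(f"all k must be >= 2, got {ks[0]}")
    vals = feature.values[observed]
    m = vals.size
    parts = []
    for k in ks:
        if m == 0:
            parts.append(Partition(np.zeros(0, dtype=np.int32), k, 0, False))
            continue
        p = quantile_partition(vals, k)
        if k > m:
            p = dataclasses.replace(p, valid=False)
        parts.append(p)
    return PartitionSet(feature.id, tuple(parts))
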