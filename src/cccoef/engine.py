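"""The clustermatch correlation coefficient (CCC) for pairs and matrices.

For a feature pair (x, y) the coefficient is

    CCC(x, y) = max(0, max over valid partition pairs (p_x, p_y) of ARI(p_x, p_y))

where numeric features contribute one quantile partition per cluster count k
in the configured range and categorical features contribute their single
label-induced partition.  The maximisation over partition resolutions is what
lets one statistic capture linear, monotone-nonlinear and subgroup-structured
relationships on numeric, categorical or mixed pairs; clipping at zero keeps
the coefficient in [0, 1], since negative ARIs indicate less-than-chance
agreement, which carries no association signal.

``ccc_pairwise`` runs all feature pairs of a matrix into a condensed
upper-triangle vector.  Partitions of fully observed features are computed
once and reused across every pair; a pair touching a feature with missing
values is recomputed from scratch on its pairwise-complete samples, so the
coefficient never depends on an imputation model.  Results are bit-identical
for any backend and chunk size (cells are independent; the reduction is pure
assignment).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from ._kernels import best_ari_pair, ccc_block
from .ari import partition_arrays
from .errors import ParameterError, ShapeError
from .partitioning import (
    CATEGORICAL,
    FeatureVector,
    Partition,
    PartitionSet,
    categorical_partition,
    precompute_partitions,
    quantile_partition,
)

DEFAULT_K_RANGE = tuple(range(2, 11))


@dataclass(frozen=True)
class CccConfig:
    """Knobs of the coefficient.

    k_range
        Cluster counts tried for numeric features; default {2..10}, the
        published clustermatch default.  More partitions cost linearly more
        ARI evaluations per pair.
    min_pairwise_samples
        Pairs with fewer pairwise-complete samples yield an undefined result
        (not an error); below ~10 samples a k=2 quantile split is dominated
        by noise.
    backend
        'reference' (plain per-pair loop) or 'parallel' (chunked block
        evaluation).  Bit-identical outputs; performance only.
    chunk_size
        Number of condensed cells evaluated per block in the parallel
        backend.  Performance only, never changes results.
    """

    k_range: tuple = DEFAULT_K_RANGE
    min_pairwise_samples: int = 10
    backend: str = "parallel"
    chunk_size: int = 4096

    def __post_init__(self) -> None:
        ks = tuple(sorted(set(int(k) for k in self.k_range)))
        if not ks:
            raise ParameterError("k_range must be non-empty")
        if ks[0] < 2:
            raise ParameterError(f"all k in k_range must be >= 2, got {ks[0]}")
        if self.min_pairwise_samples < 2:
            raise ParameterError("min_pairwise_samples must be >= 2")
        if self.backend not in ("reference", "parallel"):
            raise ParameterError(f"unknown backend {self.backend!r}")
        if self.chunk_size < 1:
            raise ParameterError("chunk_size must be >= 1")
        object.__setattr__(self, "k_range", ks)


@dataclass(frozen=True)
class CccResult:
    """Coefficient for one pair.

    ``defined`` is False (and ``value`` NaN) when too few pairwise-complete
    samples remain or no valid partition pair exists.  ``best_k_x`` /
    ``best_k_y`` identify the argmax partition pair (ties broken toward the
    smallest k_x, then k_y).
    """

    value: float
    defined: bool
    best_k_x: Optional[int]
    best_k_y: Optional[int]
    n_used: int


@dataclass(frozen=True)
class CondensedMatrix:
    """Upper-triangle (i < j) coefficient vector over all feature pairs.

    Entry (i, j) sits at index ``i*n - i*(i+1)//2 + (j - i - 1)``.  Undefined
    coefficients are stored as NaN ("NA" on disk).  The CCC engine also fills
    the optional per-pair bookkeeping arrays (argmax ks, samples used).
    """

    n_features: int
    feature_ids: tuple
    values: np.ndarray
    best_k_x: Optional[np.ndarray] = None
    best_k_y: Optional[np.ndarray] = None
    n_used: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = self.n_features
        expected = n * (n - 1) // 2
        values = np.asarray(self.values, dtype=float)
        if values.shape != (expected,):
            raise ShapeError(f"values must have length n(n-1)/2 = {expected}, got {values.shape}")
        if len(self.feature_ids) != n:
            raise ShapeError("feature_ids length must equal n_features")
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "values", values)

    def get(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return float(self.values[condensed_index(i, j, self.n_features)])

    def pair_indices(self):
        """(i, j) row/column indices in condensed order."""
        return np.triu_indices(self.n_features, k=1)

    def to_square(self, diagonal: float = np.nan) -> np.ndarray:
        out = np.full((self.n_features, self.n_features), diagonal)
        ii, jj = self.pair_indices()
        out[ii, jj] = self.values
        out[jj, ii] = self.values
        return out


def condensed_index(i: int, j: int, n: int) -> int:
    """Map a strict upper-triangle pair (i < j < n) to its condensed index."""
    if not (0 <= i < j < n):
        raise IndexError(f"need 0 <= i < j < n, got i={i}, j={j}, n={n}")
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def _pair_partitions(feature: FeatureVector, mask: np.ndarray, k_range: Sequence[int]):
    """Partitions of a feature restricted to the pairwise-complete samples."""
    vals = feature.values[mask]
    if feature.dtype == CATEGORICAL:
        return [categorical_partition(vals)]
    parts = []
    m = vals.size
    for k in k_range:
        p = quantile_partition(vals, k)
        if k > m:
            p = dataclasses.replace(p, valid=False)
        parts.append(p)
    return parts


def _stack(parts) -> tuple:
    n = parts[0].n
    P = len(parts)
    labels = np.zeros((P, n), dtype=np.int32)
    ks = np.zeros(P, dtype=np.int64)
    valid = np.zeros(P, dtype=np.bool_)
    for i, p in enumerate(parts):
        labels[i] = p.labels
        ks[i] = p.k
        valid[i] = p.valid
    return labels, ks, valid


_UNDEFINED = CccResult(float("nan"), False, None, None, 0)


def ccc_pair(x: FeatureVector, y: FeatureVector, config: CccConfig | None = None) -> CccResult:
    """Clustermatch coefficient for one feature pair.

    Missing samples are removed pairwise before partitioning.  Returns an
    undefined result (never raises) when fewer than
    ``config.min_pairwise_samples`` complete samples remain or no valid
    partition pair exists, so all-vs-all scans survive bad features.
    """
    cfg = config or CccConfig()
    if x.n_samples != y.n_samples:
        raise ShapeError(f"features {x.id!r} and {y.id!r} have different sample counts")
    mask = ~(x.missing_mask | y.missing_mask)
    n_used = int(mask.sum())
    if n_used < cfg.min_pairwise_samples:
        return dataclasses.replace(_UNDEFINED, n_used=n_used)
    px = _pair_partitions(x, mask, cfg.k_range)
    py = _pair_partitions(y, mask, cfg.k_range)
    lx, kx, vx = _stack(px)
    ly, ky, vy = _stack(py)
    best, bu, bv = best_ari_pair(lx, kx, vx, ly, ky, vy)
    if bu < 0:
        return dataclasses.replace(_UNDEFINED, n_used=n_used)
    value = best if best > 0.0 else 0.0
    return CccResult(float(value), True, int(kx[bu]), int(ky[bv]), n_used)


def ccc_pairwise(features: Sequence[FeatureVector], config: CccConfig | None = None) -> CondensedMatrix:
    """All-vs-all clustermatch coefficients as a condensed matrix.

    Partitions of fully observed features are precomputed once; pairs where
    either feature has missing values fall back to :func:`ccc_pair` on their
    pairwise-complete samples.  Output is bit-identical for any backend and
    chunk_size.
    """
    cfg = config or CccConfig()
    F = len(features)
    if F < 2:
        raise ParameterError("need at least 2 features")
    n = features[0].n_samples
    for f in features:
        if f.n_samples != n:
            raise ShapeError(f"feature {f.id!r} has {f.n_samples} samples, expected {n}")
    ids = tuple(f.id for f in features)
    npairs = F * (F - 1) // 2
    values = np.full(npairs, np.nan)
    best_kx = np.full(npairs, -1, dtype=np.int64)
    best_ky = np.full(npairs, -1, dtype=np.int64)
    n_used = np.zeros(npairs, dtype=np.int64)

    fully = np.array([not f.missing_mask.any() for f in features], dtype=bool)
    max_parts = max(len(cfg.k_range), 1)
    labels = np.zeros((F, max_parts, n), dtype=np.int32)
    ks = np.zeros((F, max_parts), dtype=np.int64)
    valid = np.zeros((F, max_parts), dtype=np.bool_)
    for f_idx, f in enumerate(features):
        if not fully[f_idx]:
            continue  # handled per-pair below
        pset = precompute_partitions(f, cfg.k_range)
        la, ka, va = partition_arrays(pset)
        labels[f_idx, : la.shape[0]] = la
        ks[f_idx, : la.shape[0]] = ka
        valid[f_idx, : la.shape[0]] = va

    ii64, jj64 = (a.astype(np.int64) for a in np.triu_indices(F, k=1))
    fast = fully[ii64] & fully[jj64]

    if cfg.backend == "parallel":
        for start in range(0, npairs, cfg.chunk_size):
            stop = min(start + cfg.chunk_size, npairs)
            ccc_block(labels, ks, valid, ii64, jj64, start, stop, values, best_kx, best_ky)
    else:
        for idx in range(npairs):
            i, j = int(ii64[idx]), int(jj64[idx])
            best, bu, bv = best_ari_pair(labels[i], ks[i], valid[i], labels[j], ks[j], valid[j])
            if bu < 0:
                values[idx] = np.nan
            else:
                values[idx] = best if best > 0.0 else 0.0
                best_kx[idx] = bu
                best_ky[idx] = bv

    # translate partition indices to cluster counts; fill n_used for fast pairs
    for idx in np.flatnonzero(fast):
        n_used[idx] = n
        if best_kx[idx] >= 0:
            best_kx[idx] = ks[ii64[idx], best_kx[idx]]
            best_ky[idx] = ks[jj64[idx], best_ky[idx]]

    # pairs touching missing values: pairwise-complete recomputation
    for idx in np.flatnonzero(~fast):
        i, j = int(ii64[idx]), int(jj64[idx])
        r = ccc_pair(features[i], features[j], cfg)
        n_used[idx] = r.n_used
        if r.defined:
            values[idx] = r.value
            best_kx[idx] = r.best_k_x
            best_ky[idx] = r.best_k_y
        else:
            values[idx] = np.nan
            best_kx[idx] = -1
            best_ky[idx] = -1

    return CondensedMatrix(F, ids, values, best_kx, best_ky, n_used)


def write_pairs_tsv(matrix: CondensedMatrix, path) -> None:
    """Long-format TSV: feature_i, feature_j, ccc, best_k_x, best_k_y, n_used.

    Undefined coefficients are written as "NA"; floats use shortest
    round-trip representation so a write/read cycle is lossless.
    """
    ii, jj = matrix.pair_indices()
    with open(path, "w") as fh:
        fh.write("feature_i\tfeature_j\tccc\tbest_k_x\tbest_k_y\tn_used\n")
        for idx in range(matrix.values.shape[0]):
            v = matrix.values[idx]
            val = "NA" if math.isnan(v) else repr(float(v))
            bkx = "NA" if matrix.best_k_x is None or matrix.best_k_x[idx] < 0 else str(int(matrix.best_k_x[idx]))
            bky = "NA" if matrix.best_k_y is None or matrix.best_k_y[idx] < 0 else str(int(matrix.best_k_y[idx]))
            nu = "NA" if matrix.n_used is None else str(int(matrix.n_used[idx]))
            fh.write(
                f"{matrix.feature_ids[ii[idx]]}\t{matrix.feature_ids[jj[idx]]}\t{val}\t{bkx}\t{bky}\t{nu}\n"
            )
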