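"""Permutation significance for the clustermatch coefficient.

The null model permutes one feature's sample order, breaking the joint
pairing while preserving both marginal distributions — the standard
exchangeable null for association statistics.  Two uses:

* :func:`permutation_pvalue` — per-pair add-one p-value
  ``p = (1 + #{null >= observed}) / (1 + P)``, never exactly zero at finite P;
* :func:`permutation_threshold` — a dataset-level "high coefficient" cutoff:
  the q-quantile of a pooled null built from P randomly drawn feature pairs,
  each with one member's sample order independently permuted.  Per-pair nulls
  over all pairs would be quadratic-cost; the pooled quantile is the
  configurable scheme used for permutation-mode tiering.

When both features are fully observed, permuting the feature is equivalent to
permuting its precomputed partition labels, which is how the fast path avoids
re-partitioning at every permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import best_ari_pair
from .ari import partition_arrays
from .engine import CccConfig, ccc_pair
from .errors import DegenerateInputError, InsufficientDataError, ParameterError
from .partitioning import FeatureVector, precompute_partitions


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perms: int
    seed: int


def _permuted_feature(y: FeatureVector, perm: np.ndarray) -> FeatureVector:
    return FeatureVector(y.id, y.values[perm], y.dtype, y.missing_mask[perm])


def permutation_pvalue(
    x: FeatureVector,
    y: FeatureVector,
    n_perms: int,
    seed: int,
    config: CccConfig | None = None,
) -> PermutationResult:
    """Add-one permutation p-value for CCC(x, y).

    Deterministic given ``seed``.  Raises :class:`InsufficientDataError` when
    the observed pair itself is not computable.
    """
    if n_perms < 1:
        raise ParameterError("n_perms must be >= 1")
    cfg = config or CccConfig()
    obs = ccc_pair(x, y, cfg)
    if not obs.defined:
        raise InsufficientDataError(
            f"pair ({x.id!r}, {y.id!r}) not computable: n_used={obs.n_used}"
        )
    rng = np.random.default_rng(seed)
    n = x.n_samples
    nulls = np.full(n_perms, np.nan)
    fast = not (x.missing_mask.any() or y.missing_mask.any())
    if fast:
        lx, kx, vx = partition_arrays(precompute_partitions(x, cfg.k_range))
        ly, ky, vy = partition_arrays(precompute_partitions(y, cfg.k_range))
        for t in range(n_perms):
            perm = rng.permutation(n)
            lyp = np.ascontiguousarray(ly[:, perm])
            best, bu, _ = best_ari_pair(lx, kx, vx, lyp, ky, vy)
            if bu >= 0:
                nulls[t] = best if best > 0.0 else 0.0
    else:
        for t in range(n_perms):
            perm = rng.permutation(n)
            r = ccc_pair(x, _permuted_feature(y, perm), cfg)
            if r.defined:
                nulls[t] = r.value
    exceed = int(np.sum(nulls >= obs.value))  # NaN compares False
    p = (1 + exceed) / (1 + n_perms)
    return PermutationResult(obs.value, nulls, float(p), n_perms, seed)


def permutation_threshold(
    features,
    n_perms: int,
    q: float,
    seed: int,
    config: CccConfig | None = None,
) -> float:
    """q-quantile of a pooled CCC null over randomly drawn permuted pairs.

    Each of the P draws picks two distinct features uniformly (with
    replacement across draws) and permutes one member's sample order.
    Deterministic given ``seed``; monotone non-decreasing in ``q``.
    """
    if len(features) < 2:
        raise ParameterError("need at least 2 features")
    if n_perms < 1:
        raise ParameterError("n_perms must be >= 1")
    if not (0.0 < q <= 1.0):
        raise ParameterError(f"q must be in (0, 1], got {q}")
    cfg = config or CccConfig()
    F = len(features)
    n = features[0].n_samples
    rng = np.random.default_rng(seed)

    fully = [not f.missing_mask.any() for f in features]
    stacked = [
        partition_arrays(precompute_partitions(f, cfg.k_range)) if fully[i] else None
        for i, f in enumerate(features)
    ]

    nulls = np.full(n_perms, np.nan)
    for t in range(n_perms):
        i = int(rng.integers(F))
        j = int(rng.integers(F - 1))
        if j >= i:
            j += 1
        perm = rng.permutation(n)
        if stacked[i] is not None and stacked[j] is not None:
            lx, kx, vx = stacked[i]
            ly, ky, vy = stacked[j]
            lyp = np.ascontiguousarray(ly[:, perm])
            best, bu, _ = best_ari_pair(lx, kx, vx, lyp, ky, vy)
            if bu >= 0:
                nulls[t] = best if best > 0.0 else 0.0
        else:
            r = ccc_pair(features[i], _permuted_feature(features[j], perm), cfg)
            if r.defined:
                nulls[t] = r.value
    pool = nulls[np.isfinite(nulls)]
    if pool.size == 0:
        raise DegenerateInputError("no computable permuted pairs in the null pool")
    return float(np.quantile(pool, q))
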