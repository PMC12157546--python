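"""Compiled inner loops shared by every ARI/CCC code path.

All backends — the scalar API, the reference loop and the chunked parallel
contract — funnel through :func:`ari_from_labels`, so backend equivalence is
bit-exact by construction.  Pair-count sums are accumulated in int64
(``m*(m-1)//2`` stays exact up to tens of thousands of samples, the division
is deferred to a single float64 operation), matching the overflow-safe scheme
used by the pure-Python :func:`cccoef.ari.adjusted_rand_index`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ari_from_labels(l1, l2, k1, k2):  # pragma: no cover - exercised via wrappers
    """Adjusted Rand Index between two label vectors (values in [0,k)).

    Returns 0.0 when max-index equals expected-index (both partitions
    effectively trivial): such partitions carry no association information.
    """
    n = l1.shape[0]
    cont = np.zeros((k1, k2), dtype=np.int64)
    for s in range(n):
        cont[l1[s], l2[s]] += 1
    a = np.zeros(k1, dtype=np.int64)
    b = np.zeros(k2, dtype=np.int64)
    sum_nij2 = np.int64(0)
    for i in range(k1):
        for j in range(k2):
            c = cont[i, j]
            a[i] += c
            b[j] += c
            sum_nij2 += c * (c - 1) // 2
    sa = np.int64(0)
    for i in range(k1):
        sa += a[i] * (a[i] - 1) // 2
    sb = np.int64(0)
    for j in range(k2):
        sb += b[j] * (b[j] - 1) // 2
    cn = np.int64(n) * np.int64(n - 1) // 2
    expected = (sa * sb) / cn
    max_index = (sa + sb) / 2.0
    denom = max_index - expected
    if denom == 0.0:
        return 0.0
    return (sum_nij2 - expected) / denom


@njit(cache=True)
def ari_matrix(lx, kx, vx, ly, ky, vy, out):  # pragma: no cover
    """Fill ``out[u, v]`` with ARI for every valid partition pair; NaN elsewhere."""
    for u in range(lx.shape[0]):
        for v in range(ly.shape[0]):
            if vx[u] and vy[v]:
                out[u, v] = ari_from_labels(lx[u], ly[v], kx[u], ky[v])
            else:
                out[u, v] = np.nan


@njit(cache=True)
def best_ari_pair(lx, kx, vx, ly, ky, vy):  # pragma: no cover
    """Maximum ARI over all valid partition pairs.

    Returns ``(best, u, v)`` with ``u = v = -1`` when no valid pair exists.
    Iteration order is ascending (u, v) with a strict ``>`` update, so argmax
    ties break toward the smallest k_x, then smallest k_y.
    """
    best = -2.0
    bu = -1
    bv = -1
    for u in range(lx.shape[0]):
        if not vx[u]:
            continue
        for v in range(ly.shape[0]):
            if not vy[v]:
                continue
            a = ari_from_labels(lx[u], ly[v], kx[u], ky[v])
            if a > best:
                best = a
                bu = u
                bv = v
    return best, bu, bv


@njit(cache=True)
def ccc_block(labels, ks, valid, ii, jj, start, stop, out_val, out_bu, out_bv):  # pragma: no cover
    """Evaluate a contiguous block of condensed indices.

    Pure per-cell assignment (no accumulation), which is what makes the
    chunked parallel contract bit-identical for any chunk size.
    """
    for idx in range(start, stop):
        i = ii[idx]
        j = jj[idx]
        best, bu, bv = best_ari_pair(labels[i], ks[i], valid[i], labels[j], ks[j], valid[j])
        if bu < 0:
            out_val[idx] = np.nan
            out_bu[idx] = -1
            out_bv[idx] = -1
        else:
            out_val[idx] = best if best > 0.0 else 0.0
            out_bu[idx] = bu
            out_bv[idx] = bv
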