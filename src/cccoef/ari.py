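"""Adjusted Rand Index between sample partitions, scalar and batched.

The ARI is the chance-corrected pair-counting agreement between two
partitions of the same objects.  From the contingency table ``n_ij`` with row
sums ``a_i``, column sums ``b_j`` and total ``n``:

    index     = sum_ij C(n_ij, 2)
    expected  = sum_i C(a_i, 2) * sum_j C(b_j, 2) / C(n, 2)
    max_index = (sum_i C(a_i, 2) + sum_j C(b_j, 2)) / 2
    ARI       = (index - expected) / (max_index - expected)

It equals 1 iff the partitions are identical up to label renaming and is 0 in
expectation under random independent labellings with fixed marginals.  The
all-vs-all clustermatch engine spends almost all of its time here, which is
why the batched form (:func:`ari_batch`) is defined as a backend contract:
chunked, independent evaluation of cells with a deterministic pure-assignment
reduction, so every backend is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import ari_from_labels, ari_matrix
from .errors import DegenerateInputError, ParameterError, ShapeError
from .partitioning import Partition, PartitionSet

BACKENDS = ("reference", "parallel")


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation counts of two partitions plus marginals."""

    counts: np.ndarray
    row_sums: np.ndarray
    col_sums: np.ndarray
    n: int


@dataclass(frozen=True)
class AriBatchResult:
    """ARI for every partition pair of two partition sets.

    ``values[u, v]`` is finite wherever ``validity_mask[u, v]`` is True;
    cells involving an invalid partition are NaN and masked False.
    """

    values: np.ndarray
    validity_mask: np.ndarray


def contingency_table(p1: Partition, p2: Partition) -> ContingencyTable:
    """Cross-tabulate two partitions of the same samples."""
    if p1.n != p2.n:
        raise ShapeError(f"partition lengths differ: {p1.n} vs {p2.n}")
    k1, k2 = p1.k, p2.k
    idx = p1.labels.astype(np.int64) * k2 + p2.labels
    counts = np.bincount(idx, minlength=k1 * k2).reshape(k1, k2).astype(np.int64)
    return ContingencyTable(counts, counts.sum(axis=1), counts.sum(axis=0), int(p1.n))


def adjusted_rand_index(table: ContingencyTable) -> float:
    """ARI from a contingency table.

    Mirrors the compiled kernel's arithmetic exactly (int64 pair-count sums,
    one deferred float64 division), so scalar and batched paths agree to the
    bit.  Returns 0.0 on a zero denominator — both partitions effectively
    trivial, a defensive path since invalid partitions are masked upstream.
    """
    if table.n < 2:
        raise DegenerateInputError(f"ARI needs n >= 2 samples, got {table.n}")
    c = table.counts.astype(np.int64, copy=False)
    sum_nij2 = np.int64((c * (c - 1) // 2).sum())
    a = table.row_sums.astype(np.int64, copy=False)
    b = table.col_sums.astype(np.int64, copy=False)
    sa = np.int64((a * (a - 1) // 2).sum())
    sb = np.int64((b * (b - 1) // 2).sum())
    cn = np.int64(table.n) * np.int64(table.n - 1) // 2
    expected = (sa * sb) / cn
    max_index = (sa + sb) / 2.0
    denom = max_index - expected
    if denom == 0.0:
        return 0.0
    return float((sum_nij2 - expected) / denom)


def ari(p1: Partition, p2: Partition) -> float:
    """Convenience: ARI of two partitions in one call."""
    return adjusted_rand_index(contingency_table(p1, p2))


def partition_arrays(pset: PartitionSet):
    """Stack a PartitionSet into (labels, ks, valid) arrays for the kernels."""
    P = len(pset)
    n = pset.n
    labels = np.zeros((P, n), dtype=np.int32)
    ks = np.zeros(P, dtype=np.int64)
    valid = np.zeros(P, dtype=np.bool_)
    for i, p in enumerate(pset.partitions):
        labels[i] = p.labels
        ks[i] = p.k
        valid[i] = p.valid
    return labels, ks, valid


def ari_batch(px: PartitionSet, py: PartitionSet, backend: str = "parallel") -> AriBatchResult:
    """ARI for every (partition of x, partition of y) combination.

    Both backends return bit-identical results: ``reference`` loops over cells
    through the scalar path, ``parallel`` evaluates the batch through the
    compiled kernel; both share the same arithmetic.
    """
    if backend not in BACKENDS:
        raise ParameterError(f"backend must be one of {BACKENDS}, got {backend!r}")
    if px.n != py.n:
        raise ShapeError(f"partition sets have incompatible lengths: {px.n} vs {py.n}")
    U, V = len(px), len(py)
    values = np.full((U, V), np.nan)
    vx = np.array([p.valid for p in px.partitions], dtype=bool)
    vy = np.array([p.valid for p in py.partitions], dtype=bool)
    validity = np.outer(vx, vy)
    if backend == "reference":
        for u in range(U):
            if not vx[u]:
                continue
            for v in range(V):
                if not vy[v]:
                    continue
                values[u, v] = adjusted_rand_index(contingency_table(px[u], py[v]))
    else:
        lx, kx, vxa = partition_arrays(px)
        ly, ky, vya = partition_arrays(py)
        ari_matrix(lx, kx, vxa, ly, ky, vya, values)
    return AriBatchResult(values, validity)
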