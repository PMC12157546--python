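"""Comparison of CCC against Pearson and Spearman: tiers, intersections,
disagreement ranking, and gene-metadata correlation.

The analysis mirrors a three-method agreement study: every feature pair gets
a coefficient per method, each method's pairs are tiered high / low / neither
(top and bottom fractions, or a permutation-null threshold), and pairs are
grouped by their tier triple.  Agreement groups are all-high or all-low
triples; *disagreement* groups are the five triples where CCC is high and at
least one of Pearson/Spearman is low — the candidate nonlinear relationships.
The top disagreements (largest CCC) are then interpreted by correlating the
genes involved against sample metadata (sex, cohort, BMI, age, ...), which is
where the coefficient's mixed numeric/categorical support pays off.

Pearson and Spearman magnitudes (absolute values) are tiered by default:
"high correlation" in the intersection analysis is about strength, and
sign-reversal patterns (Simpson-type subgroup structure) produce strong
*negative* product-moment coefficients that must still count as detections
for those methods.  Signed tiering is available via ``absolute=False``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import CccConfig, CondensedMatrix, ccc_pair, ccc_pairwise
from .errors import AlignmentError, DegenerateInputError, ParameterError, ShapeError
from .partitioning import CATEGORICAL, FeatureVector
from .significance import permutation_threshold

logger = logging.getLogger("cccoef")

TIERS = ("high", "low", "neither")

#: the five tier triples (ccc, pearson, spearman) that define disagreement:
#: CCC high and at least one other method low
DISAGREEMENT_GROUPS = (
    ("high", "low", "low"),
    ("high", "low", "neither"),
    ("high", "neither", "low"),
    ("high", "low", "high"),
    ("high", "high", "low"),
)
AGREEMENT_GROUPS = (("high", "high", "high"), ("low", "low", "low"))


@dataclass(frozen=True)
class TierAssignment:
    """Per-pair high/low/neither labels for one method."""

    method: str
    tiers: np.ndarray
    high_cutoff: float
    low_cutoff: float
    mode: str

    @property
    def n_pairs(self) -> int:
        return int(self.tiers.shape[0])


@dataclass(frozen=True)
class IntersectionTable:
    """Counts of pairs per (ccc, pearson, spearman) tier triple.

    ``table`` has one row per possible triple (27 rows, zero counts included)
    with its agreement/disagreement/other class; the three per-pair tier
    arrays are retained so downstream selection can recover pair membership.
    """

    table: pd.DataFrame
    ccc_tiers: np.ndarray
    pearson_tiers: np.ndarray
    spearman_tiers: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.ccc_tiers.shape[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def linear_coefficients(features: Sequence[FeatureVector]):
    """Pearson and Spearman condensed matrices over all numeric feature pairs.

    Pairwise-complete observations; constant features yield NaN for all their
    pairs.  Layout matches :func:`cccoef.engine.ccc_pairwise`.
    """
    F = len(features)
    if F < 2:
        raise ParameterError("need at least 2 features")
    for f in features:
        if f.dtype == CATEGORICAL:
            raise ParameterError(f"feature {f.id!r} is categorical; linear coefficients need numeric features")
    ids = tuple(f.id for f in features)
    X = np.vstack([np.where(f.missing_mask, np.nan, f.values) for f in features])
    df = pd.DataFrame(X.T)
    iu = np.triu_indices(F, k=1)
    pear = df.corr(method="pearson", min_periods=2).to_numpy()[iu]
    spear = df.corr(method="spearman", min_periods=2).to_numpy()[iu]
    return (
        CondensedMatrix(F, ids, pear),
        CondensedMatrix(F, ids, spear),
    )


def classify_tiers(
    coeffs: CondensedMatrix,
    high_pct: float = 0.30,
    low_pct: float = 0.30,
    *,
    absolute: bool = False,
    method: str = "ccc",
    mode: str = "percentile",
    high_cutoff: Optional[float] = None,
    low_cutoff: Optional[float] = None,
) -> TierAssignment:
    """Assign each pair to high / low / neither for one method.

    Percentile mode: the top ``high_pct`` fraction of *defined* entries tier
    high and the bottom ``low_pct`` tier low, cutoffs taken at order
    statistics with inclusive (>= / <=) comparisons so ties at a cutoff are
    never silently dropped (counts may then exceed the exact fraction).
    Permutation mode takes explicit cutoffs (the high one typically from
    :func:`cccoef.significance.permutation_threshold`).  Undefined (NaN)
    coefficients always tier neither.  If every defined value is equal, both
    rules match everything; high takes precedence.
    """
    vals = coeffs.values
    tv = np.abs(vals) if absolute else vals
    defined = np.isfinite(tv)
    if not defined.any():
        raise DegenerateInputError("no defined coefficients to tier")
    dvals = tv[defined]
    if mode == "percentile":
        if not (0.0 < high_pct <= 1.0):
            raise ParameterError(f"high_pct must be in (0, 1], got {high_pct}")
        if not (0.0 <= low_pct <= 1.0) or high_pct + low_pct > 1.0 + 1e-12:
            raise ParameterError("need 0 <= low_pct and high_pct + low_pct <= 1")
        hi = float(np.quantile(dvals, 1.0 - high_pct, method="higher"))
        lo = float(np.quantile(dvals, low_pct, method="lower")) if low_pct > 0 else -np.inf
    elif mode == "permutation":
        if high_cutoff is None:
            raise ParameterError("permutation mode requires high_cutoff")
        hi = float(high_cutoff)
        lo = float(low_cutoff) if low_cutoff is not None else -np.inf
    else:
        raise ParameterError(f"mode must be 'percentile' or 'permutation', got {mode!r}")
    if hi < lo:
        raise ParameterError(f"high_cutoff {hi} < low_cutoff {lo}")
    tiers = np.full(vals.shape[0], "neither", dtype=object)
    high = defined & (tv >= hi)
    low = defined & ~high & (tv <= lo)
    tiers[high] = "high"
    tiers[low] = "low"
    return TierAssignment(method, tiers, hi, lo, mode)


def _triple_class(ccc_t: str, p_t: str, s_t: str) -> str:
    triple = (ccc_t, p_t, s_t)
    if triple in AGREEMENT_GROUPS:
        return "agreement"
    if triple in DISAGREEMENT_GROUPS:
        return "disagreement"
    return "other"


def intersection_counts(
    tiers_ccc: TierAssignment,
    tiers_pearson: TierAssignment,
    tiers_spearman: TierAssignment,
) -> IntersectionTable:
    """Aggregate per-pair tier triples into the 27-row intersection table."""
    n = tiers_ccc.n_pairs
    if tiers_pearson.n_pairs != n or tiers_spearman.n_pairs != n:
        raise ShapeError("tier assignments cover different pair index spaces")
    code = {t: i for i, t in enumerate(TIERS)}
    key = (
        np.array([code[t] for t in tiers_ccc.tiers]) * 9
        + np.array([code[t] for t in tiers_pearson.tiers]) * 3
        + np.array([code[t] for t in tiers_spearman.tiers])
    )
    counts = np.bincount(key, minlength=27)
    rows = []
    for idx, (c, p, s) in enumerate(itertools.product(TIERS, TIERS, TIERS)):
        rows.append(
            {
                "ccc_tier": c,
                "pearson_tier": p,
                "spearman_tier": s,
                "class": _triple_class(c, p, s),
                "count": int(counts[idx]),
            }
        )
    table = pd.DataFrame(rows, columns=["ccc_tier", "pearson_tier", "spearman_tier", "class", "count"])
    return IntersectionTable(table, tiers_ccc.tiers, tiers_pearson.tiers, tiers_spearman.tiers)


def select_top_disagreements(
    table: IntersectionTable,
    coeffs_ccc: CondensedMatrix,
    top_k: int = 100,
    *,
    pearson: Optional[CondensedMatrix] = None,
    spearman: Optional[CondensedMatrix] = None,
) -> pd.DataFrame:
    """Rank pairs from the five CCC-high / other-low disagreement groups.

    Sorted by CCC descending, ties broken by condensed index ascending; at
    most ``top_k`` rows.  Returns an empty frame when nothing qualifies.
    """
    if top_k < 1:
        raise ParameterError("top_k must be >= 1")
    if table.n_pairs != coeffs_ccc.values.shape[0]:
        raise ShapeError("intersection table and coefficient matrix cover different pair spaces")
    qualifies = (table.ccc_tiers == "high") & (
        (table.pearson_tiers == "low") | (table.spearman_tiers == "low")
    )
    idx = np.flatnonzero(qualifies)
    cols = ["feature_i", "feature_j", "ccc", "pearson", "spearman", "group"]
    if idx.size == 0:
        return pd.DataFrame(columns=cols)
    vals = coeffs_ccc.values[idx]
    order = np.lexsort((idx, -vals))
    idx = idx[order][:top_k]
    ii, jj = coeffs_ccc.pair_indices()
    ids = coeffs_ccc.feature_ids
    return pd.DataFrame(
        {
            "feature_i": [ids[ii[t]] for t in idx],
            "feature_j": [ids[jj[t]] for t in idx],
            "ccc": coeffs_ccc.values[idx],
            "pearson": pearson.values[idx] if pearson is not None else np.nan,
            "spearman": spearman.values[idx] if spearman is not None else np.nan,
            "group": [
                f"ccc_high|pearson_{table.pearson_tiers[t]}|spearman_{table.spearman_tiers[t]}"
                for t in idx
            ],
        },
        columns=cols,
    )


def gene_metadata_correlation(
    expression,
    metadata,
    pairs: pd.DataFrame,
    config: CccConfig | None = None,
) -> pd.DataFrame:
    """CCC of every gene appearing in ``pairs`` against every metadata variable.

    ``expression`` and ``metadata`` are FeatureMatrix / MetadataTable objects
    (see :mod:`cccoef.io`) sharing the same sample IDs.  Mixed numeric vs
    categorical pairs are handled natively by the coefficient.  Variables with
    all samples missing are excluded with a logged warning.  Rows are sorted
    by CCC descending within each gene.
    """
    cfg = config or CccConfig()
    if list(expression.sample_ids) != list(metadata.sample_ids):
        exp_only = sorted(set(expression.sample_ids) - set(metadata.sample_ids))
        meta_only = sorted(set(metadata.sample_ids) - set(expression.sample_ids))
        raise AlignmentError(
            "sample IDs do not align; "
            f"expression-only: {exp_only[:10]}, metadata-only: {meta_only[:10]}"
        )
    genes: list[str] = []
    for col in ("feature_i", "feature_j"):
        for g in pairs[col]:
            if g not in genes:
                genes.append(g)
    by_id = {f.id: f for f in expression.features}
    missing_genes = [g for g in genes if g not in by_id]
    if missing_genes:
        raise AlignmentError(f"genes absent from expression matrix: {missing_genes[:10]}")
    variables = []
    for var in metadata.variables:
        if var.missing_mask.all():
            logger.warning("metadata variable %r has all samples missing; excluded", var.id)
            continue
        variables.append(var)
    rows = []
    for gene in genes:
        gf = by_id[gene]
        gene_rows = []
        for var in variables:
            r = ccc_pair(gf, var, cfg)
            gene_rows.append(
                {
                    "gene": gene,
                    "metadata_variable": var.id,
                    "ccc": r.value if r.defined else np.nan,
                    "n_used": r.n_used,
                }
            )
        gene_rows.sort(key=lambda d: (-(d["ccc"]) if np.isfinite(d["ccc"]) else np.inf))
        rows.extend(gene_rows)
    return pd.DataFrame(rows, columns=["gene", "metadata_variable", "ccc", "n_used"])


def _linear_permutation_threshold(features, n_perms, q, seed, absolute=True):
    """Pooled permutation null threshold for |Pearson| (or signed Pearson).

    Same scheme as the CCC pooled null: P random feature pairs, one member
    permuted, q-quantile of the pooled coefficients.
    """
    rng = np.random.default_rng(seed)
    F = len(features)
    n = features[0].n_samples
    nulls = np.full(n_perms, np.nan)
    for t in range(n_perms):
        i = int(rng.integers(F))
        j = int(rng.integers(F - 1))
        if j >= i:
            j += 1
        perm = rng.permutation(n)
        a = np.where(features[i].missing_mask, np.nan, features[i].values)
        b = np.where(features[j].missing_mask, np.nan, features[j].values)[perm]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
            continue
        r = float(np.corrcoef(a[ok], b[ok])[0, 1])
        nulls[t] = abs(r) if absolute else r
    pool = nulls[np.isfinite(nulls)]
    if pool.size == 0:
        raise DegenerateInputError("no computable permuted pairs in the linear null pool")
    return float(np.quantile(pool, q))


@dataclass(frozen=True)
class ComparisonResult:
    """Everything the three-method comparison pipeline produces."""

    ccc: CondensedMatrix
    pearson: CondensedMatrix
    spearman: CondensedMatrix
    tiers: dict
    intersections: IntersectionTable
    top_disagreements: pd.DataFrame
    thresholds: dict


def run_comparison(
    features: Sequence[FeatureVector],
    *,
    config: CccConfig | None = None,
    tier_mode: str = "percentile",
    high_pct: float = 0.30,
    low_pct: float = 0.30,
    n_perms: int = 500,
    q: float = 0.99,
    seed: int = 0,
    top_k: int = 100,
    absolute: bool = True,
) -> ComparisonResult:
    """End-to-end three-method comparison on one expression matrix.

    This is the single source of truth behind the ``compare`` CLI subcommand.
    In permutation tier mode the high cutoffs come from pooled permutation
    nulls (per method) at quantile ``q``; low cutoffs stay at the bottom
    ``low_pct`` percentile (a permutation null only defines "high").
    """
    cfg = config or CccConfig()
    ccc_cm = ccc_pairwise(features, cfg)
    pear_cm, spear_cm = linear_coefficients(features)
    thresholds: dict = {"mode": tier_mode}
    if tier_mode == "percentile":
        t_ccc = classify_tiers(ccc_cm, high_pct, low_pct, method="ccc")
        t_p = classify_tiers(pear_cm, high_pct, low_pct, absolute=absolute, method="pearson")
        t_s = classify_tiers(spear_cm, high_pct, low_pct, absolute=absolute, method="spearman")
    elif tier_mode == "permutation":
        thr_ccc = permutation_threshold(features, n_perms, q, seed, cfg)
        thr_lin = _linear_permutation_threshold(features, n_perms, q, seed + 1, absolute=absolute)
        thresholds.update({"ccc_high": thr_ccc, "linear_high": thr_lin, "q": q, "n_perms": n_perms})

        def _low(cm, use_abs):
            tv = np.abs(cm.values) if use_abs else cm.values
            d = tv[np.isfinite(tv)]
            return float(np.quantile(d, low_pct, method="lower")) if low_pct > 0 else -np.inf

        t_ccc = classify_tiers(
            ccc_cm, method="ccc", mode="permutation", high_cutoff=thr_ccc, low_cutoff=_low(ccc_cm, False)
        )
        t_p = classify_tiers(
            pear_cm, absolute=absolute, method="pearson", mode="permutation",
            high_cutoff=thr_lin, low_cutoff=_low(pear_cm, absolute),
        )
        t_s = classify_tiers(
            spear_cm, absolute=absolute, method="spearman", mode="permutation",
            high_cutoff=thr_lin, low_cutoff=_low(spear_cm, absolute),
        )
    else:
        raise ParameterError(f"tier_mode must be 'percentile' or 'permutation', got {tier_mode!r}")
    itab = intersection_counts(t_ccc, t_p, t_s)
    top = select_top_disagreements(itab, ccc_cm, top_k, pearson=pear_cm, spearman=spear_cm)
    return ComparisonResult(
        ccc_cm, pear_cm, spear_cm,
        {"ccc": t_ccc, "pearson": t_p, "spearman": t_s},
        itab, top, thresholds,
    )
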