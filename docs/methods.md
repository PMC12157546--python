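# Methods

## The coefficient

The clustermatch correlation coefficient of a feature pair is the maximum
Adjusted Rand Index over all pairs of per-feature partitions, clipped to
[0, 1]. Numeric features are partitioned by empirical quantiles at every
cluster count k in a configured range; categorical features contribute the
single partition induced by their labels, with category names mapped to
integer codes in lexicographic order so runs are reproducible across
platforms. The maximisation searches partition resolutions: a coarse k = 2
split captures group structure (dimorphic expression), finer splits capture
smooth nonlinear dependence, and the clip at zero discards
less-than-chance agreement, which carries no association signal.

**Quantile partition.** Sample i receives label `min(floor(q_i · k), k − 1)`
with `q_i = (midrank_i − 0.5) / n`. Using midranks guarantees that equal
values always share a label (ties never straddle a cluster boundary); with
tie-free data and k | n, cluster sizes are exactly equal, otherwise they
differ by at most one as ties permit. Exact sizes under heavy ties are
implementation-defined; only the coherence invariant is contractual. Because
labels depend on values only through ranks, the partition — and hence the
coefficient — is invariant under strictly increasing transforms of tie-free
features, and CCC is exactly 1.0 for any monotone relationship.

**Partition validity.** A partition is valid iff it has at least two
non-empty clusters; partitions with k exceeding the number of non-missing
samples are flagged invalid. Invalid partitions are excluded from the
maximisation; when no valid pair exists (for example a constant feature), the
result is an *undefined* coefficient — a NaN sentinel ("NA" on disk), never
an exception, so a single bad feature cannot abort an all-vs-all run.

**ARI arithmetic.** Pair-count sums Σ C(m, 2) are accumulated in 64-bit
integers with the division deferred to a single float64 operation, which
keeps the computation exact up to tens of thousands of samples. A zero
denominator (both partitions effectively trivial) returns 0.0; this path is
defensive only, since invalid partitions are masked upstream. The scalar
Python implementation mirrors the compiled kernel's operation sequence
exactly, so scalar and batched results agree to the bit.

## Backend contract

The batched ARI evaluation is the hot loop of an all-vs-all scan, so it is
defined as a *contract* rather than a runtime: cells (partition-pair or
feature-pair) are evaluated independently in contiguous chunks of condensed
indices, and the reduction is pure assignment — no accumulation order to
vary. Consequently the `reference` backend (plain per-pair loop) and the
`parallel` backend (chunked block evaluation through the numba kernel) are
bit-identical for every chunk size, which the tests assert. A multi-process
or GPU realization is an optional extension that must pass the same
bit-equivalence test; double-precision semantics are part of the contract.

## Missing data

Missing values are removed pairwise, per feature pair, before partitioning —
never imputed, so coefficient semantics cannot depend on an imputation model.
Partitions of fully observed features are computed once and reused across all
pairs (the reuse that makes all-vs-all scans cheap); a pair touching a
feature with missing values is recomputed from scratch on its
pairwise-complete samples. Pairs with fewer than `min_pairwise_samples`
(default 10) complete samples are undefined: below roughly ten samples a
k = 2 quantile split is noise-dominated.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `k_range` | {2, …, 10} | cluster counts tried per numeric feature (the published clustermatch default); cost grows with its square per pair |
| `min_pairwise_samples` | 10 | pairwise-complete sample floor below which a pair is undefined |
| `backend`, `chunk_size` | parallel, 4096 | performance only; never change results |
| `high_pct`, `low_pct` | 0.30, 0.30 | tier fractions (top/bottom 30% of defined pairs) |
| `n_perms` (P), `q` | 500, 0.99 | pooled permutation null size and quantile for permutation-mode thresholds |
| `top_k` | 100 | disagreement pairs retained for metadata interpretation |

## Significance

The null permutes one feature's sample order, breaking the joint pairing
while preserving both marginals — the standard exchangeable null. Per-pair
p-values use the add-one estimator `p = (1 + #{null ≥ observed}) / (1 + P)`,
which is never zero at finite P and is uniform on its discrete support under
the null. Dataset-level "high" thresholds are the q-quantile of a *pooled*
null built from P randomly drawn feature pairs, each with one member
permuted; per-pair nulls over all pairs would be quadratic-cost, and the
pooled quantile is the scheme used for permutation-mode tiering (it is
exposed as configuration, since the construction is genuinely open). When a
feature is fully observed, permuting it is equivalent to permuting its
precomputed partition labels, which is how the null avoids re-partitioning at
every draw.

## Tiering and intersections

Each method's pairs are tiered high / low / neither. Percentile mode takes
the cutoffs at order statistics of the *defined* coefficients (undefined
pairs carry no rank information and always tier neither) with inclusive
comparisons, so ties at a cutoff are all included rather than silently
dropped; if every defined value is equal, high takes precedence — a
deterministic, documented resolution unreachable on real data. Pearson and
Spearman are tiered by *magnitude* by default: "high correlation" in the
intersection analysis is about strength, and Simpson-type reversals produce
strong negative coefficients that must count as detections for those methods.
Signed tiering is available (`absolute=False`); the choice genuinely matters
for sign-reversal patterns, which are disagreements under signed tiering but
not under magnitude tiering.

Pairs are grouped by their (CCC, Pearson, Spearman) tier triple. Agreement
groups are all-high and all-low. The five triples with CCC high and at least
one other method low — (low, low), (low, neither), (neither, low),
(low, high), (high, low) — form the disagreement class, the unique
enumeration consistent with three-state tiers; disagreement pairs are ranked
by CCC descending (ties by condensed index) and the top pairs are carried
into gene–metadata correlation.

## Synthetic data

The generators emulate the relationship archetypes the analysis exists to
find, each deterministic in its spec: monotone; quadratic with x mirrored
exactly symmetric about zero (so the sample third moment, and hence Pearson,
vanishes by construction at zero noise); two-group linear (signal in one
group, constant zero in the other — the chromosome-Y archetype); Simpson
reversal, where the group offset is solved in closed form from the realized
draws so the pooled least-squares slope equals −slope exactly while both
within-group slopes stay positive (construction-guaranteed, not
sampled-for, and verified by assertion); masked subset; and independent
null. Noise is additive Gaussian — the simplest model that exercises
rank/partition robustness. Defaults: noise_sd 0.05 on unit-scale signals for
single-pair fixtures, 0.02 for planted-matrix recovery studies (emulating the
visually tight exemplar patterns); planted-recovery runs use 50 features ×
200 samples with 5 monotone + 5 quadratic planted pairs.

What the fixtures deliberately do **not** model: negative-binomial count
noise, library-size effects, inter-gene correlation structure, outliers or
batch effects. Passing tests therefore demonstrate the coefficient's
*semantics* (what patterns it can represent and rank), not performance on raw
RNA-seq counts, which should be normalised upstream as usual.

## Numerical and design choices

- Argmax ties over partition pairs break toward the smallest k_x, then k_y
  (ascending iteration, strict improvement), so `best_k` bookkeeping is
  deterministic.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; CLI runs record the seed in `run_config.json`.
- Floats are serialized with shortest round-trip representation, making
  write/read cycles lossless and repeated runs byte-identical.
- The null calibration bound used in tests (95th percentile of the n = 100
  null coefficient below 0.15) was measured at 0.057 over 500 independent
  pairs; the p-value uniformity check uses a Kolmogorov–Smirnov bound of
  0.14, the 99.9th percentile of an exact-null oracle simulation (10,000
  replicates of 200 draws from the discrete add-one support), frozen before
  use.
- Problem sizes in tests and the acceptance script (30×50 determinism
  matrices, n = 100 calibration pairs, 50×200 planted recovery, 500×200
  spot-checked scan) were chosen as the smallest sizes at which each
  property is cleanly identified.

## Known limitations

- The coefficient is undirected and detects *association strength*, not
  shape; interpreting a disagreement pair still requires looking at the data
  (hence the metadata-correlation step).
- Quantile partitioning needs enough distinct values; heavily tied or
  low-cardinality numeric features degrade toward categorical behaviour.
- The pooled permutation threshold assumes features are exchangeable draws
  from a common null; strong heteroskedasticity across features would argue
  for stratified pooling.
- The parallel backend is realized as sequential chunked evaluation; it
  parallelises trivially, but no multi-process executor ships in this
  package.
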