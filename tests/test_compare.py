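import logging

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from cccoef import (
    CccConfig,
    CondensedMatrix,
    FeatureMatrix,
    FixtureSpec,
    MetadataTable,
    categorical_feature,
    ccc_pairwise,
    classify_tiers,
    gene_metadata_correlation,
    generate_matrix,
    intersection_counts,
    linear_coefficients,
    numeric_feature,
    run_comparison,
    select_top_disagreements,
)
from cccoef.errors import AlignmentError, DegenerateInputError, ParameterError


def direct_pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


class TestLinearCoefficients:
    def test_affine_pair_is_one(self):
        x = np.arange(20, dtype=float)
        feats = [numeric_feature("x", x), numeric_feature("y", 2 * x + 1)]
        pear, spear = linear_coefficients(feats)
        assert pear.values[0] == pytest.approx(1.0)
        assert spear.values[0] == pytest.approx(1.0)

    def test_monotone_nonlinear_separates_methods(self):
        x = np.linspace(0, 5, 30)
        feats = [numeric_feature("x", x), numeric_feature("y", np.exp(x))]
        pear, spear = linear_coefficients(feats)
        assert spear.values[0] == pytest.approx(1.0)
        assert pear.values[0] < 1.0

    def test_matches_textbook_formulas(self, rng):
        data = rng.normal(size=(20, 50))
        feats = [numeric_feature(f"g{i}", data[i]) for i in range(20)]
        pear, spear = linear_coefficients(feats)
        idx = 0
        for i in range(20):
            for j in range(i + 1, 20):
                assert pear.values[idx] == pytest.approx(direct_pearson(data[i], data[j]), abs=1e-12)
                assert spear.values[idx] == pytest.approx(
                    direct_pearson(rankdata(data[i]), rankdata(data[j])), abs=1e-12
                )
                idx += 1

    def test_constant_feature_yields_nan(self, rng):
        feats = [numeric_feature("c", np.full(30, 2.5)), numeric_feature("x", rng.normal(size=30))]
        pear, spear = linear_coefficients(feats)
        assert np.isnan(pear.values[0]) and np.isnan(spear.values[0])

    def test_categorical_rejected(self):
        feats = [numeric_feature("x", np.arange(10.0)), categorical_feature("c", list("ababababab"))]
        with pytest.raises(ParameterError):
            linear_coefficients(feats)


def cm_from_values(values):
    values = np.asarray(values, dtype=float)
    m = len(values)
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    return CondensedMatrix(n, tuple(f"f{i}" for i in range(n)), values)


class TestClassifyTiers:
    def test_ten_ranked_values_default_cutoffs(self):
        cm = cm_from_values([v / 10 for v in range(1, 11)])
        t = classify_tiers(cm)
        tiers = dict(zip([v / 10 for v in range(1, 11)], t.tiers))
        assert [tiers[v / 10] for v in (8, 9, 10)] == ["high"] * 3
        assert [tiers[v / 10] for v in (1, 2, 3)] == ["low"] * 3
        assert [tiers[v / 10] for v in (4, 5, 6, 7)] == ["neither"] * 4

    def test_boundary_everything_high(self):
        cm = cm_from_values([0.1, 0.5, 0.9])
        t = classify_tiers(cm, high_pct=1.0, low_pct=0.0)
        assert list(t.tiers) == ["high"] * 3

    def test_all_equal_values_tier_high(self):
        cm = cm_from_values([0.4, 0.4, 0.4])
        t = classify_tiers(cm)
        assert list(t.tiers) == ["high"] * 3

    def test_nan_entries_tier_neither(self):
        cm = cm_from_values([0.9, np.nan, 0.1])
        t = classify_tiers(cm)
        assert list(t.tiers) == ["high", "neither", "low"]

    def test_absolute_mode_ranks_magnitudes(self):
        cm = cm_from_values([-0.95, 0.05, 0.5])
        t = classify_tiers(cm, high_pct=1 / 3, low_pct=1 / 3, absolute=True)
        assert list(t.tiers) == ["high", "low", "neither"]

    def test_permutation_mode_uses_explicit_cutoff(self):
        cm = cm_from_values([0.9, 0.2, 0.05])
        t = classify_tiers(cm, mode="permutation", high_cutoff=0.5, low_cutoff=0.1)
        assert list(t.tiers) == ["high", "neither", "low"]
        assert t.mode == "permutation"

    def test_invalid_fractions_rejected(self):
        cm = cm_from_values([0.1, 0.2, 0.3])
        with pytest.raises(ParameterError):
            classify_tiers(cm, high_pct=0.0)
        with pytest.raises(ParameterError):
            classify_tiers(cm, high_pct=0.6, low_pct=0.6)

    def test_all_nan_rejected(self):
        cm = cm_from_values([np.nan, np.nan, np.nan])
        with pytest.raises(DegenerateInputError):
            classify_tiers(cm)


@pytest.fixture(scope="module")
def planted_quadratic_run():
    spec = FixtureSpec("quadratic", n_samples=100, noise_sd=0.02, seed=42)
    matrix, truth = generate_matrix(20, 100, [((0, 1), spec)], seed=7)
    res = run_comparison(matrix.features, seed=1)
    return matrix, truth, res


class TestIntersections:
    def test_counts_conserved_over_27_groups(self, planted_quadratic_run):
        _, _, res = planted_quadratic_run
        table = res.intersections.table
        assert len(table) == 27
        assert table["count"].sum() == res.intersections.n_pairs == 20 * 19 // 2

    def test_identical_rankings_have_zero_disagreement(self, rng):
        vals = rng.uniform(0, 1, 10)
        tiers = [classify_tiers(cm_from_values(vals), method=m) for m in ("ccc", "pearson", "spearman")]
        itab = intersection_counts(*tiers)
        dis = itab.table[itab.table["class"] == "disagreement"]
        assert dis["count"].sum() == 0
        agree = itab.table[itab.table["class"] == "agreement"]
        assert agree["count"].sum() == 6  # 3 high + 3 low of 10 values

    def test_planted_quadratic_lands_in_disagreement_group(self, planted_quadratic_run):
        _, truth, res = planted_quadratic_run
        itab = res.intersections
        # condensed index of planted pair (features 0, 1) is 0
        assert itab.ccc_tiers[0] == "high"
        assert itab.pearson_tiers[0] == "low" or itab.spearman_tiers[0] == "low"

    def test_agreement_class_definition(self, planted_quadratic_run):
        _, _, res = planted_quadratic_run
        table = res.intersections.table
        for _, row in table.iterrows():
            triple = (row.ccc_tier, row.pearson_tier, row.spearman_tier)
            if row["class"] == "agreement":
                assert triple in (("high",) * 3, ("low",) * 3)
            elif row["class"] == "disagreement":
                assert triple[0] == "high" and "low" in triple[1:]


class TestTopDisagreements:
    def test_planted_pair_ranks_first(self, planted_quadratic_run):
        _, truth, res = planted_quadratic_run
        top = res.top_disagreements
        assert len(top) >= 1
        assert (top.iloc[0].feature_i, top.iloc[0].feature_j) == (
            truth.iloc[0].feature_i,
            truth.iloc[0].feature_j,
        )

    def test_top_k_larger_than_pool_returns_all(self, planted_quadratic_run):
        _, _, res = planted_quadratic_run
        full = select_top_disagreements(res.intersections, res.ccc, top_k=10_000)
        limited = select_top_disagreements(res.intersections, res.ccc, top_k=1)
        assert len(limited) == 1
        assert len(full) <= 10_000
        assert full.iloc[0].ccc == limited.iloc[0].ccc

    def test_ccc_sorted_descending_with_index_tiebreak(self):
        vals = np.array([0.9, 0.9, 0.2, 0.9, 0.1, 0.05])  # 4 features -> 6 pairs
        cm = cm_from_values(vals)
        t_ccc = classify_tiers(cm, high_pct=0.5, low_pct=0.3)
        all_low = classify_tiers(
            cm_from_values(np.zeros(6)), mode="permutation", high_cutoff=10.0, low_cutoff=1.0,
            method="pearson",
        )
        assert set(all_low.tiers) == {"low"}
        itab = intersection_counts(t_ccc, all_low, all_low)
        top = select_top_disagreements(itab, cm, top_k=10)
        assert list(top.ccc) == sorted(top.ccc, reverse=True)
        # the three tied 0.9 pairs sit at condensed indices 0, 1, 3 -> pairs
        # (f0,f1), (f0,f2), (f1,f2) in that order
        assert list(zip(top.feature_i, top.feature_j)) == [("f0", "f1"), ("f0", "f2"), ("f1", "f2")]

    def test_no_qualifying_pairs_gives_empty_frame(self, rng):
        vals = rng.uniform(0, 1, 6)
        tiers = [classify_tiers(cm_from_values(vals), method=m) for m in ("ccc", "pearson", "spearman")]
        itab = intersection_counts(*tiers)
        top = select_top_disagreements(itab, cm_from_values(vals))
        assert len(top) == 0


class TestGeneMetadata:
    def _dimorphic_setup(self, n=100):
        rng = np.random.default_rng(77)
        x = rng.uniform(0.1, 1.0, n)
        sex = np.array(["M"] * (n // 2) + ["F"] * (n // 2), dtype=object)
        gene = np.where(sex == "M", 1.5 * x, 0.0)
        expression = FeatureMatrix(
            [numeric_feature("dimorphic_gene", gene), numeric_feature("noise_gene", rng.normal(size=n))],
            [f"S{i:04d}" for i in range(n)],
        )
        metadata = MetadataTable(
            [categorical_feature("sex", sex), numeric_feature("bmi", rng.normal(27, 4, n))],
            [f"S{i:04d}" for i in range(n)],
        )
        pairs = pd.DataFrame({"feature_i": ["dimorphic_gene"], "feature_j": ["noise_gene"]})
        return expression, metadata, pairs

    def test_noise_free_dimorphic_gene_vs_sex_is_one(self):
        expression, metadata, pairs = self._dimorphic_setup()
        table = gene_metadata_correlation(expression, metadata, pairs)
        row = table[(table.gene == "dimorphic_gene") & (table.metadata_variable == "sex")]
        assert row.ccc.iloc[0] == 1.0

    def test_noise_gene_stays_near_zero(self):
        expression, metadata, pairs = self._dimorphic_setup()
        table = gene_metadata_correlation(expression, metadata, pairs)
        noise_rows = table[table.gene == "noise_gene"]
        assert (noise_rows.ccc < 0.15).all()

    def test_rows_sorted_by_ccc_within_gene(self):
        expression, metadata, pairs = self._dimorphic_setup()
        table = gene_metadata_correlation(expression, metadata, pairs)
        for _, sub in table.groupby("gene", sort=False):
            vals = sub.ccc.to_numpy()
            assert all(vals[i] >= vals[i + 1] for i in range(len(vals) - 1))

    def test_all_missing_variable_excluded_with_warning(self, caplog):
        expression, metadata, pairs = self._dimorphic_setup()
        metadata = MetadataTable(
            metadata.variables + [numeric_feature("empty", np.full(100, np.nan))],
            metadata.sample_ids,
        )
        with caplog.at_level(logging.WARNING, logger="cccoef"):
            table = gene_metadata_correlation(expression, metadata, pairs)
        assert "empty" not in set(table.metadata_variable)
        assert any("empty" in rec.message for rec in caplog.records)

    def test_unaligned_samples_raise_listing_offenders(self):
        expression, metadata, pairs = self._dimorphic_setup()
        bad_meta = MetadataTable(metadata.variables, ["X0"] + metadata.sample_ids[1:])
        with pytest.raises(AlignmentError, match="X0"):
            gene_metadata_correlation(expression, bad_meta, pairs)
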