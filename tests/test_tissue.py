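import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elisl.cellline import call_alterations
from elisl.data_io import GenePair, OmicsBundle
from elisl.tissue import (
    GROUP_CO_ALTERED,
    SUBGROUP_ONE_ONLY,
    SUBGROUP_UNALTERED,
    TISSUE_FEATURE_NAMES,
    avg_expression_features,
    cna_correlation_features,
    coexpression_features,
    comutation_grouping,
    family_comutation_survival,
    survival_feature,
    tissue_feature_block,
)

from conftest import make_tissue_bundle


def survival_cohort(co_altered, times, events, ages=None, sexes=None):
    """Minimal two-gene tissue bundle whose co-mutation grouping equals the
    given boolean mask (both genes mutated exactly where the mask is set)."""
    n = len(co_altered)
    samples = [f"P{i}" for i in range(n)]
    genes = ["A", "B"]
    rows = []
    for i, co in enumerate(co_altered):
        if co:
            rows.append((samples[i], "A", "missense"))
            rows.append((samples[i], "B", "missense"))
    mutations = pd.DataFrame(rows, columns=["sample", "gene", "variant_class"])
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "time_months": times,
            "event": events,
            "age": ages if ages is not None else np.full(n, 60.0),
            "sex": sexes if sexes is not None else ["F"] * n,
            "cancer": "BRCA",
        }
    )
    return OmicsBundle(
        samples=samples, genes=genes, mutations=mutations, clinical=clinical
    )


class TestComutationGrouping:
    def test_cross_omics_alteration_suffices(self):
        """gene_a mutated and gene_b expression-altered in the same sample
        counts as co-altered."""
        samples, genes = ["P1", "P2"], ["A", "B"]
        bundle = OmicsBundle(
            samples=samples,
            genes=genes,
            mutations=pd.DataFrame(
                {"sample": ["P1"], "gene": ["A"], "variant_class": ["missense"]}
            ),
            expr_z=pd.DataFrame({"A": [0.0, 0.0], "B": [2.5, 2.5]}, index=samples),
        )
        grouping = comutation_grouping(GenePair("A", "B"), bundle)
        assert bool(grouping.co_altered["P1"])
        assert not bool(grouping.co_altered["P2"])  # alteration in B only

    def test_no_alterations_all_not_co_altered(self):
        samples, genes = ["P1", "P2"], ["A", "B"]
        bundle = OmicsBundle(
            samples=samples,
            genes=genes,
            expr_z=pd.DataFrame(0.0, index=samples, columns=genes),
        )
        grouping = comutation_grouping(GenePair("A", "B"), bundle)
        assert not grouping.co_altered.any()
        assert (grouping.subgroup == SUBGROUP_UNALTERED).all()

    def test_partition_exhaustive_and_disjoint(self, tissue_bundle):
        grouping = comutation_grouping(GenePair("A", "B"), tissue_bundle)
        sizes = grouping.group_sizes
        assert sum(sizes.values()) == len(tissue_bundle.samples)


class TestSurvivalFeature:
    def test_planted_hazard_detected(self):
        """n=500, exponential survival, hazard ratio 0.3 for the co-altered
        group: the Wald test should clearly reject."""
        rng = np.random.default_rng(2)
        n = 500
        co = rng.random(n) < 0.3
        hazard = (1 / 60) * np.where(co, 0.3, 1.0)
        t = rng.exponential(1 / hazard)
        c = rng.uniform(20, 150, n)
        bundle = survival_cohort(
            co,
            np.minimum(t, c),
            (t <= c).astype(int),
            ages=rng.normal(60, 8, n),
            sexes=rng.choice(["F", "M"], n),
        )
        p = survival_feature(GenePair("A", "B"), bundle)
        assert p < 0.05

    def test_zero_co_altered_gives_missing(self):
        rng = np.random.default_rng(3)
        n = 50
        bundle = survival_cohort(
            np.zeros(n, dtype=bool), rng.exponential(60, n), np.ones(n, dtype=int)
        )
        assert np.isnan(survival_feature(GenePair("A", "B"), bundle))

    def test_missing_clinical_gives_missing(self, tissue_bundle):
        stripped = OmicsBundle(
            samples=tissue_bundle.samples,
            genes=tissue_bundle.genes,
            mutations=tissue_bundle.mutations,
            expr_z=tissue_bundle.expr_z,
        )
        assert np.isnan(survival_feature(GenePair("A", "B"), stripped))


class TestAvgExpressionFeatures:
    def test_arithmetic_on_log_scale(self):
        """expr(A)=[2,4,6] raw; B altered in sample 3 only."""
        samples, genes = ["P1", "P2", "P3"], ["A", "B"]
        bundle = OmicsBundle(
            samples=samples,
            genes=genes,
            expr_level=pd.DataFrame(
                {"A": [2.0, 4.0, 6.0], "B": [1.0, 1.0, 1.0]}, index=samples
            ),
            mutations=pd.DataFrame(
                {"sample": ["P3"], "gene": ["B"], "variant_class": ["missense"]}
            ),
        )
        feats = avg_expression_features(GenePair("A", "B"), bundle)
        expect_unalt = np.mean([np.log2(3.0), np.log2(5.0)])
        assert feats[0] == pytest.approx(expect_unalt)
        assert feats[1] == pytest.approx(np.log2(7.0))

    def test_no_altered_samples_gives_missing(self):
        samples, genes = ["P1", "P2"], ["A", "B"]
        bundle = OmicsBundle(
            samples=samples,
            genes=genes,
            expr_level=pd.DataFrame(1.0, index=samples, columns=genes),
            expr_z=pd.DataFrame(0.0, index=samples, columns=genes),
        )
        feats = avg_expression_features(GenePair("A", "B"), bundle)
        assert np.isnan(feats[1]) and np.isnan(feats[3])

    def test_oracle_equivalence_random_instances(self):
        """Agrees with a loop-based brute force on 100 random 10x4 cohorts."""
        from test_cellline import brute_force_pair_means

        rng = np.random.default_rng(7)
        genes = ["A", "B", "C", "D"]
        for _ in range(100):
            samples = [f"P{i}" for i in range(10)]
            level = pd.DataFrame(
                rng.lognormal(2, 1, size=(10, 4)), index=samples, columns=genes
            )
            z = pd.DataFrame(
                rng.standard_normal((10, 4)) * 2, index=samples, columns=genes
            )
            bundle = OmicsBundle(samples=samples, genes=genes, expr_level=level, expr_z=z)
            i, j = rng.choice(4, size=2, replace=False)
            pair = GenePair(genes[i], genes[j])
            got = avg_expression_features(pair, bundle)
            alt = call_alterations(bundle, "any").frame
            want = brute_force_pair_means(pair, np.log2(level + 1), alt)
            np.testing.assert_allclose(got, want, equal_nan=True)


class TestCoexpressionFeatures:
    def _bundle(self, a, b):
        samples = [f"P{i}" for i in range(len(a))]
        return OmicsBundle(
            samples=samples,
            genes=["A", "B"],
            expr_level=pd.DataFrame({"A": a, "B": b}, index=samples),
        )

    def test_perfect_correlation(self):
        x = np.linspace(1, 10, 10)
        feats = coexpression_features(GenePair("A", "B"), self._bundle(x, 2 * x + 1))
        # log transform preserves monotone increase but not exact linearity;
        # construct exact linearity on the log scale instead
        a = 2.0 ** np.linspace(1, 5, 10) - 1
        b = 2.0 ** (2 * np.linspace(1, 5, 10)) - 1
        feats = coexpression_features(GenePair("A", "B"), self._bundle(a, b))
        assert feats[0] == pytest.approx(1.0)
        assert np.isnan(feats[2]) and np.isnan(feats[4])  # no normal/healthy data

    def test_anti_correlation(self):
        x = np.linspace(1, 5, 8)
        a = 2.0**x - 1
        b = 2.0 ** (6 - x) - 1  # log2(b+1) = 6 - x, exactly anti-linear
        feats = coexpression_features(GenePair("A", "B"), self._bundle(a, b))
        assert feats[0] == pytest.approx(-1.0)

    def test_constant_vector_missing(self):
        feats = coexpression_features(
            GenePair("A", "B"), self._bundle(np.ones(10), np.arange(10.0))
        )
        assert np.isnan(feats[0]) and np.isnan(feats[1])

    def test_independence_null_distribution(self):
        """|r| < 0.1 in >= 95% of replicates for independent expression at
        n=1000."""
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(100):
            a = rng.lognormal(3, 1, 1000)
            b = rng.lognormal(3, 1, 1000)
            r = coexpression_features(GenePair("A", "B"), self._bundle(a, b))[0]
            hits += abs(r) < 0.1
        assert hits >= 95


class TestCnaCorrelationFeatures:
    def _bundle(self, a, b):
        samples = [f"P{i}" for i in range(len(a))]
        return OmicsBundle(
            samples=samples,
            genes=["A", "B"],
            cna=pd.DataFrame({"A": a, "B": b}, index=samples),
        )

    def test_identical_vectors(self):
        a = [-2, -1, 0, 1, 2, 0, 1]
        feats = cna_correlation_features(GenePair("A", "B"), self._bundle(a, a))
        assert feats[0] == pytest.approx(1.0)

    def test_rank_invariance_monotone_transform(self):
        a = np.array([-2, -1, 0, 1, 2])
        b = np.array([-2, 0, 1, 2, 2])  # monotone non-decreasing with ties
        rho = cna_correlation_features(GenePair("A", "B"), self._bundle(a, b))[0]
        rho_oracle = stats.pearsonr(stats.rankdata(a), stats.rankdata(b))[0]
        assert rho == pytest.approx(rho_oracle)

    def test_oracle_equivalence_rank_then_pearson(self):
        """Spearman rho equals Pearson on ranks, 50 random instances."""
        rng = np.random.default_rng(13)
        for _ in range(50):
            a = rng.choice([-2, -1, 0, 1, 2], 20)
            b = rng.choice([-2, -1, 0, 1, 2], 20)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            rho = cna_correlation_features(GenePair("A", "B"), self._bundle(a, b))[0]
            want = stats.pearsonr(stats.rankdata(a), stats.rankdata(b))[0]
            assert rho == pytest.approx(want)

    def test_constant_vector_missing(self):
        feats = cna_correlation_features(
            GenePair("A", "B"), self._bundle([0] * 5, [-2, -1, 0, 1, 2])
        )
        assert np.isnan(feats).all()


class TestTissueFeatureBlock:
    def test_thirteen_columns_stable_order(self, tissue_bundle):
        pairs = [GenePair("A", "B"), GenePair("C", "D")]
        block = tissue_feature_block(pairs, tissue_bundle)
        assert block.values.shape == (2, 13)
        assert block.columns == TISSUE_FEATURE_NAMES

    def test_missing_clinical_only_kills_survival_column(self, tissue_bundle):
        stripped = OmicsBundle(
            samples=tissue_bundle.samples,
            genes=tissue_bundle.genes,
            expr_z=tissue_bundle.expr_z,
            expr_level=tissue_bundle.expr_level,
            mutations=tissue_bundle.mutations,
            cna=tissue_bundle.cna,
            expr_level_normal=tissue_bundle.expr_level_normal,
            expr_level_healthy=tissue_bundle.expr_level_healthy,
        )
        pairs = [GenePair("A", "B")]
        with_clin = tissue_feature_block(pairs, tissue_bundle)
        without = tissue_feature_block(pairs, stripped)
        assert np.isnan(without.values[0, 0])
        np.testing.assert_allclose(
            with_clin.values[0, 1:], without.values[0, 1:], equal_nan=True
        )

    def test_deterministic(self, tissue_bundle):
        pairs = [GenePair("A", "C")]
        b1 = tissue_feature_block(pairs, tissue_bundle)
        b2 = tissue_feature_block(pairs, tissue_bundle)
        np.testing.assert_array_equal(b1.values, b2.values)

    def test_bounds_correlations_and_pvalues(self, small_world, small_blocks):
        block = next(b for b in small_blocks if b.source == "tissue")
        vals = block.to_frame()
        for col in ["coexpr_tumour_r", "coexpr_normal_r", "coexpr_healthy_r", "cna_spearman_rho"]:
            v = vals[col].dropna()
            assert ((v >= -1) & (v <= 1)).all()
        for col in ["survival_p", "coexpr_tumour_p", "cna_spearman_p"]:
            v = vals[col].dropna()
            assert ((v >= 0) & (v <= 1)).all()


class TestFamilyComutationSurvival:
    def test_singleton_families_reduce_to_pairwise(self, tissue_bundle):
        pair = GenePair("A", "B")
        pairwise = comutation_grouping(pair, tissue_bundle)
        result, _ = family_comutation_survival(["A"], ["B"], tissue_bundle, min_group_size=1)
        assert result.group_sizes[GROUP_CO_ALTERED] == int(pairwise.co_altered.sum())
        assert result.group_sizes[SUBGROUP_ONE_ONLY] == int(
            (pairwise.subgroup == SUBGROUP_ONE_ONLY).sum()
        )

    def test_disjoint_family_all_not_co_altered(self, tissue_bundle):
        result, curves = family_comutation_survival(
            ["A"], ["ZZZ1", "ZZZ2"], tissue_bundle
        )
        assert result.group_sizes[GROUP_CO_ALTERED] == 0
        assert np.isnan(result.p_value)
        assert "not-co-altered" in curves  # curves still emitted

    def test_planted_median_survival_difference(self):
        """Co-altered group with twice the median survival: the KM medians
        recover the planted 2x difference within 20% (n=600)."""
        rng = np.random.default_rng(21)
        n = 600
        co = rng.random(n) < 0.4
        med_base = 40.0
        scale = np.where(co, 2 * med_base, med_base) / np.log(2)
        t = rng.exponential(scale)
        c = rng.uniform(150, 400, n)
        bundle = survival_cohort(co, np.minimum(t, c), (t <= c).astype(int))
        result, curves = family_comutation_survival(["A"], ["B"], bundle)
        ratio = (
            result.median_survival[GROUP_CO_ALTERED]
            / result.median_survival["not-co-altered"]
        )
        assert abs(ratio - 2.0) / 2.0 < 0.2
        assert result.p_value < 0.05

    def test_empty_family_rejected(self, tissue_bundle):
        with pytest.raises(ValueError):
            family_comutation_survival([], ["A"], tissue_bundle)
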