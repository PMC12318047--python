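import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, hypergeom, kstest

from rareburden import (
    ChromCategory,
    CmhResult,
    ConfigError,
    Consequence,
    DataError,
    GeneAnnotation,
    Phenotype,
    StratumTable,
    VariantClass,
    build_tables,
    cmh_test,
    gene_is_testable,
    run_burden_scan,
)

from conftest import make_samples, make_variant


def oracle_single_stratum(a, b, c, d):
    """Conditional score chi-square from explicit hypergeometric moments."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    e = float(np.sum(support * pmf))
    var = float(np.sum((support - e) ** 2 * pmf))
    return (a - e) ** 2 / var


class TestCmhTest:
    def test_single_table_matches_score_chi_square(self):
        t = StratumTable("s", 10, 990, 2, 998)
        res = cmh_test([t], continuity=False)
        # closed-form conditional score statistic on one 2x2
        a, b, c, d = 10, 990, 2, 998
        n = a + b + c + d
        expected = (n - 1) * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.statistic == pytest.approx(oracle_single_stratum(a, b, c, d), rel=1e-9)
        assert res.p_two_sided == pytest.approx(chi2.sf(expected, 1), rel=1e-12)
        assert res.or_mh == pytest.approx(a * d / (b * c), rel=1e-12)

    def test_identical_null_tables(self):
        tables = [StratumTable("s1", 5, 95, 5, 95), StratumTable("s2", 5, 95, 5, 95)]
        res = cmh_test(tables, continuity=False)
        assert res.or_mh == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_all_carriers_in_cases_gives_infinite_or(self):
        res = cmh_test([StratumTable("s", 4, 96, 0, 100)])
        assert math.isinf(res.or_mh)
        assert res.ci95[1] == math.inf
        assert 0 < res.p_two_sided < 1

    def test_all_carriers_in_controls_gives_zero_or(self):
        res = cmh_test([StratumTable("s", 0, 100, 4, 96)])
        assert res.or_mh == 0.0

    def test_no_informative_strata_flagged_untestable(self):
        res = cmh_test([StratumTable("s", 0, 100, 0, 100)])
        assert not res.testable
        assert res.n_informative_strata == 0

    def test_zero_margin_strata_skipped(self):
        informative = [StratumTable("s1", 3, 97, 1, 99)]
        padded = informative + [StratumTable("s2", 0, 50, 0, 50)]
        r1, r2 = cmh_test(informative), cmh_test(padded)
        assert r2.n_informative_strata == 1
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.or_mh == pytest.approx(r2.or_mh)

    def test_negative_count_is_data_error(self):
        with pytest.raises(DataError):
            StratumTable("s", -1, 10, 2, 8)

    @given(
        tables=st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)),
            min_size=1,
            max_size=4,
        )
    )
    def test_continuity_is_conservative_and_order_invariant(self, tables):
        ts = [StratumTable(f"s{i}", *t) for i, t in enumerate(tables)]
        if not any(t.informative for t in ts):
            return
        corrected = cmh_test(ts, continuity=True)
        plain = cmh_test(ts, continuity=False)
        assert corrected.p_two_sided >= plain.p_two_sided - 1e-12
        rev = cmh_test(ts[::-1], continuity=True)
        assert rev.statistic == pytest.approx(corrected.statistic, rel=1e-12, abs=1e-12)
        assert rev.or_mh == pytest.approx(corrected.or_mh, rel=1e-12, abs=1e-12) or (
            math.isnan(rev.or_mh) and math.isnan(corrected.or_mh)
        )

    def test_multi_stratum_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        tables = [
            StratumTable("s1", 10, 990, 2, 998),
            StratumTable("s2", 7, 493, 3, 497),
            StratumTable("s3", 1, 199, 2, 398),
        ]
        arr = np.array([[[t.a, t.b], [t.c, t.d]] for t in tables]).transpose(1, 2, 0)
        strat = sm.StratifiedTable(arr.astype(float))
        res = cmh_test(tables, continuity=True)
        smres = strat.test_null_odds(correction=True)
        assert res.statistic == pytest.approx(float(smres.statistic), rel=1e-10)
        assert res.p_two_sided == pytest.approx(float(smres.pvalue), rel=1e-10)
        assert res.or_mh == pytest.approx(float(strat.oddsratio_pooled), rel=1e-10)
        lcb, ucb = strat.oddsratio_pooled_confint(0.05)
        assert res.ci95[0] == pytest.approx(float(lcb), rel=1e-6)
        assert res.ci95[1] == pytest.approx(float(ucb), rel=1e-6)

    def test_permutation_p_values_are_uniform(self):
        # fixed gene with many carriers; shuffling labels within strata must
        # yield calibrated p-values
        rng = np.random.default_rng(5)
        n_per, carriers_per = 4000, 2000
        pvals = []
        for _ in range(500):
            tables = []
            for s in range(2):
                a = rng.hypergeometric(n_per, n_per, carriers_per)
                tables.append(
                    StratumTable(f"s{s}", a, n_per - a, carriers_per - a, n_per - carriers_per + a)
                )
            pvals.append(cmh_test(tables, continuity=True).p_two_sided)
        stat, p = kstest(pvals, "uniform")
        assert p >= 0.01, f"KS D={stat:.4f}, p={p:.4g}"


class TestBuildTables:
    def test_carriers_only_in_one_stratum(self):
        s1 = make_samples(5, 5, stratum="s1")
        s2 = make_samples(5, 5, stratum="s2")
        samples = s1 + s2
        v = make_variant(gene="G1", carriers=(s1[0].sample_id,))
        tables = build_tables("G1", VariantClass.PTV_ONLY, [v], samples)
        assert len(tables) == 2
        assert (tables[0].a, tables[0].c) == (1, 0)
        assert (tables[1].a, tables[1].c) == (0, 0)
        assert tables[0].a + tables[0].b == 5

    def test_carrier_counted_once_per_gene_class(self):
        samples = make_samples(3, 3)
        sid = samples[0].sample_id
        vs = [make_variant(gene="G1", carriers=(sid,)) for _ in range(3)]
        tables = build_tables("G1", VariantClass.PTV_ONLY, vs, samples)
        assert tables[0].a == 1
        allele = build_tables(
            "G1", VariantClass.PTV_ONLY, vs, samples, carrier_mode="allele"
        )
        assert allele[0].a == 3

    def test_x_nonpar_sex_split_partitions_stratum(self):
        samples = make_samples(6, 6, stratum="s1")
        v = make_variant(
            gene="GX", carriers=(samples[0].sample_id,), chrom=ChromCategory.X_NONPAR
        )
        tables = build_tables(
            "GX",
            VariantClass.PTV_ONLY,
            [v],
            samples,
            chrom_category=ChromCategory.X_NONPAR,
            sex_split_strata=("s1",),
        )
        assert len(tables) == 2
        assert sum(t.a + t.b for t in tables) == 6
        assert sum(t.c + t.d for t in tables) == 6
        assert {t.base_stratum for t in tables} == {"s1"}

    def test_autosomal_gene_ignores_sex_split(self):
        samples = make_samples(4, 4, stratum="s1")
        tables = build_tables(
            "G1", VariantClass.PTV_ONLY, [], samples, sex_split_strata=("s1",)
        )
        assert len(tables) == 1

    def test_unknown_carrier_is_data_error(self):
        samples = make_samples(2, 2)
        v = make_variant(gene="G1", carriers=("nobody",))
        with pytest.raises(DataError, match="nobody"):
            build_tables("G1", VariantClass.PTV_ONLY, [v], samples)

    def test_counts_match_brute_force_recount(self, small_null_study):
        study = small_null_study
        gene = study.genes[0].gene_id
        for vclass in (VariantClass.PTV_ONLY, VariantClass.MPC_GT2):
            tables = build_tables(gene, vclass, study.variants, study.samples)
            # brute-force recount from raw records
            from rareburden import class_membership

            by_stratum_case = {}
            by_stratum_ctl = {}
            carriers = set()
            for v in study.variants:
                if v.gene_id == gene and class_membership(v, vclass):
                    carriers |= v.carrier_ids
            for s in study.samples:
                key = s.stratum
                if s.sample_id in carriers:
                    if s.phenotype is Phenotype.CASE:
                        by_stratum_case[key] = by_stratum_case.get(key, 0) + 1
                    else:
                        by_stratum_ctl[key] = by_stratum_ctl.get(key, 0) + 1
            for t in tables:
                assert t.a == by_stratum_case.get(t.stratum, 0)
                assert t.c == by_stratum_ctl.get(t.stratum, 0)


class TestGeneIsTestable:
    def _tables(self, counts):
        return [
            StratumTable(f"s{i}", a, 100 - a, c, 100 - c)
            for i, (a, c) in enumerate(counts)
        ]

    def test_single_non_largest_stratum_excluded(self):
        ann = GeneAnnotation("G1")
        tables = self._tables([(1, 0), (0, 0)])
        assert not gene_is_testable(ann, VariantClass.PTV_ONLY, tables, "s1")

    def test_largest_stratum_alone_suffices(self):
        ann = GeneAnnotation("G1")
        tables = self._tables([(1, 0), (0, 0)])
        assert gene_is_testable(ann, VariantClass.PTV_ONLY, tables, "s0")

    def test_two_strata_suffice(self):
        ann = GeneAnnotation("G1")
        tables = self._tables([(1, 0), (0, 1)])
        assert gene_is_testable(ann, VariantClass.PTV_ONLY, tables, "s1")

    def test_clonal_haematopoiesis_gene_excluded(self):
        ann = GeneAnnotation("TET2", excluded_clonal_haem=True)
        tables = self._tables([(2, 1), (1, 1), (3, 0)])
        assert not gene_is_testable(ann, VariantClass.PTV_ONLY, tables, "s0")

    def test_missing_possible_variant_flag(self):
        ann = GeneAnnotation("G1", has_possible_mpc_gt3=False)
        tables = self._tables([(1, 1), (2, 0)])
        assert not gene_is_testable(ann, VariantClass.PTV_MPC_GT3, tables, "s0")
        assert gene_is_testable(ann, VariantClass.PTV_MPC_GT2, tables, "s0")

    def test_unknown_largest_stratum_is_config_error(self):
        ann = GeneAnnotation("G1")
        with pytest.raises(ConfigError):
            gene_is_testable(ann, VariantClass.PTV_ONLY, self._tables([(1, 1)]), "nope")


class TestRunBurdenScan:
    def test_counted_tests_four_classes(self):
        samples = make_samples(10, 10, stratum="s1") + make_samples(10, 10, stratum="s2")
        genes = [GeneAnnotation(f"G{i}") for i in range(10)]
        results = run_burden_scan([], samples, genes)
        assert len(results) == 40  # 4 classes x 10 genes, all flags set
        assert all(not r.testable for r in results)  # no carriers anywhere

    def test_flags_reduce_counted_tests(self):
        samples = make_samples(5, 5, stratum="s1") + make_samples(5, 5, stratum="s2")
        genes = [GeneAnnotation("G0")]
        genes += [GeneAnnotation("G1", has_possible_mpc_gt3=False)]
        genes += [
            GeneAnnotation("G2", has_possible_mpc_gt3=False, has_possible_mpc_gt2=False)
        ]
        results = run_burden_scan([], samples, genes)
        # G0: 4 tests; G1: PTV, PTV+MPC>2, MPC>2; G2: PTV only
        assert len(results) == 4 + 3 + 1

    def test_rare_filter_applied(self):
        samples = make_samples(50, 50, stratum="s1") + make_samples(50, 50, stratum="s2")
        sid = samples[0].sample_id
        common = make_variant(gene="G0", carriers=(sid,), mac_internal=6)
        rare = make_variant(gene="G0", carriers=(sid,), mac_internal=1)
        genes = [GeneAnnotation("G0")]
        res_common = run_burden_scan([common], samples, genes)
        res_rare = run_burden_scan([rare], samples, genes)
        assert all(not r.testable for r in res_common)
        ptv = [r for r in res_rare if r.variant_class is VariantClass.PTV_ONLY]
        assert ptv[0].testable  # carrier in the largest stratum

    def test_largest_stratum_default_is_biggest(self, small_null_study):
        study = small_null_study
        res = run_burden_scan(study.variants, study.samples, study.genes)
        # stratum0 (300+300) is the largest; genes observed only there are testable
        assert any(r.testable for r in res)
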