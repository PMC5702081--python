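"""Matrix assembly, median imputation, normalization, z-test and corrections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from guidescreen.guide_report import GuideCounts, GuideReference
from guidescreen.screen_stats import (
    adjust_pvalues,
    assemble_matrix,
    bonferroni_threshold,
    export_results,
    gene_ratios,
    gene_test,
    impute,
    normalize,
    prepare,
    results_frame,
    score_genes,
    volcano_data,
    ztest_from_ratios,
)


def make_ref(genes_to_guides: dict[str, list[str]]) -> GuideReference:
    guides, genes = [], []
    for gene, gs in genes_to_guides.items():
        guides += gs
        genes += [gene] * len(gs)
    table = pd.DataFrame({"gene": genes}, index=pd.Index(guides, name="sequence"))
    return GuideReference(table, "sequence", ("gene",))


def make_matrix(genes_to_guides, exp_counts, ctrl_counts):
    ref = make_ref(genes_to_guides)
    exp = GuideCounts(dict(zip(ref.guides, exp_counts)), 0, "exp")
    ctrl = GuideCounts(dict(zip(ref.guides, ctrl_counts)), 0, "ctrl")
    return assemble_matrix([exp], [ctrl], ref)


GENE_MAP = {"gA": ["AAAA", "CCCC"], "gB": ["GGGG", "TTTT"]}


class TestAssemble:
    def test_all_observed_no_missing(self):
        m = make_matrix(GENE_MAP, [5, 6, 7, 8], [1, 2, 3, 4])
        assert m.original.shape == (4, 2)
        assert not (m.original == 0).any().any()

    def test_zero_count_is_missing(self):
        m = make_matrix(GENE_MAP, [5, 6, 7, 8], [0, 2, 3, 4])
        assert m.original.at["AAAA", "ctrl"] == 0

    def test_replicates_give_four_columns(self):
        ref = make_ref(GENE_MAP)
        libs = [
            GuideCounts({g: 1 for g in ref.guides}, 0, label)
            for label in ("e1", "e2", "c1", "c2")
        ]
        m = assemble_matrix(libs[:2], libs[2:], ref)
        assert list(m.original.columns) == ["e1", "e2", "c1", "c2"]
        assert m.exp_labels == ["e1", "e2"]

    def test_mismatched_reference_rejected(self):
        ref = make_ref(GENE_MAP)
        good = GuideCounts({g: 1 for g in ref.guides}, 0, "exp")
        bad = GuideCounts({"XXXX": 1}, 0, "ctrl")
        with pytest.raises(ValueError, match="reference"):
            assemble_matrix([good], [bad], ref)


class TestImpute:
    def test_ones_replaced_by_pre_replacement_median(self):
        # oracle: sort [1,1,4,6,10], middle element is 4; splice into ones
        gene_map = {"g": ["A1", "A2", "A3", "A4", "A5"]}
        m = make_matrix(gene_map, [1, 4, 10, 1, 6], [2, 2, 2, 2, 2])
        out = impute(m)
        assert out.imputed["exp"].tolist() == [4.0, 4.0, 10.0, 4.0, 6.0]

    def test_missing_set_to_one_then_median(self):
        # a zero (missing) becomes 1, then joins the ones->median replacement
        gene_map = {"g": ["A1", "A2", "A3", "A4", "A5"]}
        m = make_matrix(gene_map, [0, 4, 10, 1, 6], [2, 2, 2, 2, 2])
        out = impute(m)
        assert out.imputed["exp"].tolist() == [4.0, 4.0, 10.0, 4.0, 6.0]

    def test_no_ones_unchanged(self):
        gene_map = {"g": ["A1", "A2", "A3"]}
        m = make_matrix(gene_map, [5, 7, 9], [5, 7, 9])
        out = impute(m)
        assert out.imputed["exp"].tolist() == [5.0, 7.0, 9.0]

    def test_all_ones_fixed_point(self):
        gene_map = {"g": ["A1", "A2", "A3"]}
        m = make_matrix(gene_map, [1, 1, 1], [1, 1, 1])
        out = impute(m)
        assert out.imputed["exp"].tolist() == [1.0, 1.0, 1.0]

    def test_even_guide_count_median_is_mean_of_central_pair(self):
        gene_map = {"g": ["A1", "A2", "A3", "A4"]}
        m = make_matrix(gene_map, [1, 4, 6, 100], [2, 2, 2, 2])
        out = impute(m)
        # median of [1,4,6,100] = (4+6)/2 = 5
        assert out.imputed.at["A1", "exp"] == 5.0

    def test_medians_are_per_gene_not_global(self):
        gene_map = {"gA": ["A1", "A2", "A3"], "gB": ["B1", "B2", "B3"]}
        m = make_matrix(gene_map, [1, 10, 20, 1, 100, 200], [2] * 6, )
        out = impute(m)
        assert out.imputed.at["A1", "exp"] == 10.0
        assert out.imputed.at["B1", "exp"] == 100.0


class TestNormalize:
    def test_columns_sum_to_one(self):
        gene_map = {"g": ["A1", "A2", "A3"]}
        m = normalize(impute(make_matrix(gene_map, [2, 3, 5], [4, 4, 2])))
        assert m.normalized["exp"].tolist() == [0.2, 0.3, 0.5]
        assert abs(m.normalized["ctrl"].sum() - 1.0) < 1e-12

    def test_random_matrix_columns_sum_to_one(self):
        rng = np.random.default_rng(1)
        gene_map = {f"g{i}": [f"g{i}_{j}" for j in range(5)] for i in range(20)}
        n = 100
        m = make_matrix(gene_map, rng.integers(0, 1000, n), rng.integers(0, 1000, n))
        m = prepare(m)
        sums = m.normalized.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_empty_library_errors(self):
        gene_map = {"g": ["A1"]}
        m = make_matrix(gene_map, [5], [5])
        m = impute(m)
        m.imputed["exp"] = 0.0
        with pytest.raises(ValueError, match="empty"):
            normalize(m)


class TestZTest:
    def test_frozen_example(self):
        # ratios [0.5, 1.0, 1.5]: m=1.0, s=0.5, t = 1.0/(0.5/sqrt(3))
        row = ztest_from_ratios(np.array([[0.5, 1.0, 1.5]])).iloc[0]
        assert row["mean"] == 1.0
        assert row["sd"] == 0.5
        assert abs(row["t"] - 3.4641016151377544) < 1e-12
        assert abs(row["p"] - stats.norm.sf(3.4641016151377544)) < 1e-15
        assert abs(row["p"] - 2.66e-4) < 5e-6

    def test_null_identity(self):
        gene_map = {"g": ["A1", "A2", "A3"]}
        m = prepare(make_matrix(gene_map, [3, 5, 7], [3, 5, 7]))
        res = gene_test(m, "g")
        assert res.mean == 0.0
        assert res.t == 0.0
        assert res.p == 0.5

    def test_matches_paired_ttest_statistic(self):
        """t equals scipy's paired t-test statistic on (log2 exp, log2 ctrl)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 11))
            x = rng.lognormal(size=n)
            y = rng.lognormal(size=n)
            row = ztest_from_ratios(np.log2(x / y)[None, :]).iloc[0]
            oracle = stats.ttest_rel(np.log2(x), np.log2(y)).statistic
            assert abs(row["t"] - oracle) < 1e-10

    def test_tails(self):
        r = np.array([[0.5, 1.0, 1.5]])
        t = 3.4641016151377544
        assert np.isclose(ztest_from_ratios(r, "enrichment")["p"][0], stats.norm.sf(t))
        assert np.isclose(ztest_from_ratios(r, "depletion")["p"][0], stats.norm.cdf(t))
        assert np.isclose(ztest_from_ratios(r, "two_sided")["p"][0], 2 * stats.norm.sf(t))

    def test_zero_sd_nonzero_mean_degenerate(self):
        row = ztest_from_ratios(np.array([[1.0, 1.0, 1.0]])).iloc[0]
        assert row["t"] == np.inf
        assert row["p"] == 0.0

    def test_single_ratio_gene_has_no_pvalue(self):
        gene_map = {"g1": ["A1"], "g2": ["B1", "B2"]}
        m = prepare(make_matrix(gene_map, [10, 3, 5], [2, 3, 5]))
        results = {r.gene: r for r in score_genes(m)}
        assert results["g1"].p is None
        assert results["g1"].n == 1
        assert np.isfinite(results["g1"].mean)
        # the single-ratio gene is excluded from the multiple-testing family
        assert results["g2"].p_bonf == results["g2"].p  # m = 1 tested gene

    def test_replicates_pool_ratios_per_pair(self):
        ref = make_ref({"g": ["A1", "A2"]})
        libs = {
            "e1": [10, 20], "e2": [30, 40], "c1": [5, 5], "c2": [10, 10],
        }
        counts = {k: GuideCounts(dict(zip(ref.guides, v)), 0, k) for k, v in libs.items()}
        m = prepare(assemble_matrix([counts["e1"], counts["e2"]],
                                    [counts["c1"], counts["c2"]], ref))
        r = gene_ratios(m, "g")
        assert len(r) == 4  # 2 guides x 2 replicate pairs
        x = m.normalized
        expected = np.concatenate([
            np.log2(x["e1"].to_numpy() / x["c1"].to_numpy()),
            np.log2(x["e2"].to_numpy() / x["c2"].to_numpy()),
        ])
        assert np.allclose(r, expected)

    def test_gene_test_agrees_with_test_genes(self):
        rng = np.random.default_rng(0)
        gene_map = {f"g{i}": [f"g{i}_{j}" for j in range(4)] for i in range(10)}
        m = prepare(make_matrix(gene_map, rng.integers(0, 500, 40),
                                rng.integers(0, 500, 40)))
        batch = {r.gene: r for r in score_genes(m)}
        for gene in gene_map:
            single = gene_test(m, gene)
            assert np.isclose(single.t, batch[gene].t, equal_nan=True)
            assert np.isclose(single.p, batch[gene].p)


class TestAdjustPvalues:
    def test_single_test_identity(self):
        bh, bonf = adjust_pvalues(np.array([0.03]))
        assert bh[0] == bonf[0] == 0.03

    def test_frozen_step_up_example(self):
        # oracle: sort, p_(i)*m/i, cumulative min from the largest rank
        bh, _ = adjust_pvalues(np.array([0.005, 0.01, 0.03, 0.04]))
        assert np.allclose(bh, [0.02, 0.02, 0.04, 0.04])

    def test_bonferroni_scaling(self):
        _, bonf = adjust_pvalues(np.concatenate([[1e-7], np.ones(19999)]))
        assert np.isclose(bonf[0], 0.002)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues(np.array([0.5, 1.5]))

    @staticmethod
    def bh_oracle(p):
        """Brute-force step-up: sort, scale, cumulative min from the top."""
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        adjusted = [None] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adjusted[i] = min(running, 1.0)
        return adjusted

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 200)))
            bh, _ = adjust_pvalues(p)
            assert np.allclose(bh, self.bh_oracle(p.tolist()), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.random(500)
        bh, bonf = adjust_pvalues(p)
        assert np.allclose(bh, multipletests(p, method="fdr_bh")[1])
        assert np.allclose(bonf, multipletests(p, method="bonferroni")[1])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=80))
    def test_invariants(self, plist):
        p = np.array(plist)
        bh, bonf = adjust_pvalues(p)
        assert np.all((bh >= p - 1e-15) & (bh <= 1))
        assert np.all((bonf >= p - 1e-15) & (bonf <= 1))
        assert np.all(bh <= bonf + 1e-15)
        # monotone in rank: sorting p sorts bh
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(bh[order]) >= -1e-15)


class TestThresholdAndVolcano:
    def test_genome_wide_threshold(self):
        assert bonferroni_threshold(0.05, 20000) == 0.0000025

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.01, 100, 0.0001)])
    def test_threshold_values(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_volcano_y_axis(self):
        gene_map = {f"g{i}": [f"g{i}_{j}" for j in range(3)] for i in range(3)}
        rng = np.random.default_rng(4)
        m = prepare(make_matrix(gene_map, rng.integers(2, 500, 9), rng.integers(2, 500, 9)))
        results = score_genes(m)
        table = volcano_data(results, log_base=2)
        for _, row in table.iterrows():
            assert np.isclose(row["neg_log_p"], -np.log2(row["p"]))
        # frozen spot values of the y transform
        assert np.isclose(-np.log2(0.25), 2.0)
        assert -np.log2(1.0) == 0.0

    def test_significance_uses_bonferroni_threshold(self):
        gene_map = {"hit": [f"h{j}" for j in range(5)], "null": [f"n{j}" for j in range(5)]}
        m = prepare(make_matrix(gene_map, [4000, 4200, 3900, 4100, 4050, 10, 11, 9, 10, 10],
                                [10, 11, 9, 10, 10, 10, 11, 9, 10, 10]))
        results = score_genes(m)
        table = volcano_data(results, alpha=0.05, m=20000)
        hit = table[table["gene"] == "hit"].iloc[0]
        assert hit["p"] < 0.0000025
        assert bool(hit["significant"])
        assert not table[table["gene"] == "null"]["significant"].iloc[0]


class TestProperties:
    def test_monotonicity_in_experimental_counts(self):
        gene_map = {f"g{i}": [f"g{i}_{j}" for j in range(5)] for i in range(10)}
        rng = np.random.default_rng(12)
        exp = rng.integers(2, 500, 50)
        ctrl = rng.integers(2, 500, 50)
        base = prepare(make_matrix(gene_map, exp, ctrl))
        fc_before = gene_test(base, "g0").mean
        boosted = exp.copy()
        boosted[:5] *= 3  # g0's guides
        after = prepare(make_matrix(gene_map, boosted, ctrl))
        assert gene_test(after, "g0").mean >= fc_before

    def test_scale_invariance_of_statistics(self):
        gene_map = {f"g{i}": [f"g{i}_{j}" for j in range(5)] for i in range(10)}
        rng = np.random.default_rng(13)
        exp = rng.integers(2, 500, 50)
        ctrl = rng.integers(2, 500, 50)
        r1 = results_frame(score_genes(prepare(make_matrix(gene_map, exp, ctrl))))
        r2 = results_frame(score_genes(prepare(make_matrix(gene_map, exp * 7, ctrl))))
        for col in ("log2fc", "t", "p", "p_bh", "p_bonf"):
            assert np.allclose(r1[col], r2[col], rtol=1e-12)


class TestExport:
    def test_round_trip_and_schema(self, tmp_path):
        gene_map = {f"g{i}": [f"g{i}_{j}" for j in range(4)] for i in range(3)}
        rng = np.random.default_rng(3)
        m = prepare(make_matrix(gene_map, rng.integers(0, 500, 12), rng.integers(0, 500, 12)))
        results = score_genes(m)
        path = tmp_path / "results.csv"
        export_results(m, results, path)
        df = pd.read_csv(path)
        assert len(df) == 3
        # identifiers + guides x libraries x 3 + 4 statistics
        assert df.shape[1] == 1 + 4 * 2 * 3 + 4
        for res in results:
            row = df[df["gene"] == res.gene].iloc[0]
            assert np.isclose(row["p"], res.p, rtol=1e-11)
            assert np.isclose(row["log2fc"], res.mean, rtol=1e-11)
            g0 = m.guides_of(res.gene)[0]
            assert row["guide1_exp_original"] == m.original.at[g0, "exp"]
            assert np.isclose(row["guide1_exp_normalized"], m.normalized.at[g0, "exp"],
                              rtol=1e-11)
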