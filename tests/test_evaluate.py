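import numpy as np
import pytest

from srcshave import (
    ShavingConfig,
    allele_table,
    benchmark_config,
    centroid_classify,
    fisher_select,
    fisher_table_pvalue,
    generate,
    loo_cv,
    overlap_report,
    random_select,
    src_classify,
    ttest_select,
)
from srcshave.pipeline import run_selection

from conftest import hypergeometric_two_sided, make_dataset


class TestSrcClassify:
    def test_training_case_sample_is_recovered(self):
        rng = np.random.default_rng(0)
        train = rng.normal(size=(6, 8))
        status = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert src_classify(train, status, train[:, 5]) == 1
        assert src_classify(train, status, train[:, 1]) == 0

    def test_well_separated_gaussians(self):
        rng = np.random.default_rng(3)
        nvar = 10
        mu1 = np.full(nvar, 4.0)  # 4 sigma separation
        train = np.hstack([rng.normal(0, 1, (nvar, 20)),
                           rng.normal(mu1[:, None], 1, (nvar, 20))])
        status = np.array([0] * 20 + [1] * 20)
        correct = 0
        for i in range(50):
            cls = i % 2
            y = rng.normal(mu1 if cls else 0.0, 1.0, nvar)
            correct += src_classify(train, status, y) == cls
        assert correct >= 49

    def test_equidistant_query_ties_to_control_class(self):
        # y orthogonal to every training sample: both class residuals = ||y||
        train = np.array([[1.0, 0, -1, 0], [0, 1, 0, -1], [0, 0, 0, 0]])
        status = np.array([0, 0, 1, 1])
        assert src_classify(train, status, np.array([0.0, 0.0, 1.0])) == 0

    def test_all_zero_dictionary_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            src_classify(np.zeros((3, 6)), np.array([0, 0, 0, 1, 1, 1]), np.ones(3))

    def test_needs_two_samples_per_class(self):
        with pytest.raises(ValueError, match="2 training samples"):
            src_classify(np.ones((2, 3)), np.array([0, 1, 1]), np.ones(2))


class TestLooCv:
    def test_perfectly_separating_variable_scores_100(self):
        ds = make_dataset([[0, 0, 0, 0, 1, 1, 1, 1]], [0, 0, 0, 0, 1, 1, 1, 1])
        assert loo_cv(ds, ["v1"]).cr == 100.0

    def test_shuffled_labels_on_noise_stay_near_chance(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(10, 80))
        status = np.array([0] * 40 + [1] * 40)
        rng.shuffle(status)
        ds = make_dataset(vals, status)
        cr = loo_cv(ds, [f"v{i + 1}" for i in range(10)]).cr
        assert 35.0 <= cr <= 65.0

    def test_cr_denominator_is_total_sample_count(self):
        ds = make_dataset([[0, 0, 0, 0, 0, 1, 1, 1]], [0, 0, 0, 0, 0, 1, 1, 1])
        res = loo_cv(ds, ["v1"])
        assert res.cr == 100.0 * (res.predictions == ds.status).sum() / 8
        assert set(np.unique(res.predictions)) <= {0, 1}

    def test_missing_selected_key_is_error(self):
        ds = make_dataset(np.zeros((2, 6)) + np.arange(6), [0, 0, 0, 1, 1, 1])
        with pytest.raises(KeyError):
            loo_cv(ds, ["nope"])

    def test_centroid_ablation_classifier(self):
        train = np.array([[0.0, 0.5, 1.5, 2.0]])
        status = np.array([0, 0, 1, 1])
        assert centroid_classify(train, status, np.array([0.3])) == 0
        assert centroid_classify(train, status, np.array([1.7])) == 1
        # exactly equidistant query ties toward the control class
        assert centroid_classify(train, status, np.array([1.0])) == 0
        ds = make_dataset([[0, 0, 0, 1, 1, 1]], [0, 0, 0, 1, 1, 1])
        assert loo_cv(ds, ["v1"], classifier="centroid").cr == 100.0


class TestTtestSelect:
    def test_planted_shift_ranks_first(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(101, 40))
        vals[0, 20:] += 3.0  # 3 sigma shift in cases
        ds = make_dataset(vals, [0] * 20 + [1] * 20)
        assert ttest_select(ds, 5)[0] == "v1"

    def test_constant_variables_fall_back_to_input_order(self):
        ds = make_dataset(np.ones((3, 6)), [0, 0, 0, 1, 1, 1])
        assert ttest_select(ds, 3) == ["v1", "v2", "v3"]

    def test_label_flip_preserves_ranking(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(20, 30))
        status = np.array([0] * 15 + [1] * 15)
        a = ttest_select(make_dataset(vals, status), 10)
        b = ttest_select(make_dataset(vals, 1 - status), 10)
        assert a == b


class TestFisherSelect:
    def test_extreme_table_matches_enumeration(self):
        # 5 cases all coded 2, 5 controls all coded 0 -> table [[10,0],[0,10]]
        geno = [2, 2, 2, 2, 2, 0, 0, 0, 0, 0]
        status = np.array([1] * 5 + [0] * 5)
        table = allele_table(np.array(geno, float), status)
        assert np.array_equal(table, [[10, 0], [0, 10]])
        p = fisher_table_pvalue(table)
        from math import comb
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_balanced_table_has_p_one(self):
        assert fisher_table_pvalue(np.array([[5, 5], [5, 5]])) == 1.0

    def test_homozygous_sample_contributes_two_alleles(self):
        table = allele_table(np.array([2.0, 0.0, 1.0, 0.0]), np.array([1, 1, 0, 0]))
        assert np.array_equal(table, [[2, 2], [1, 3]])

    def test_monomorphic_snp_gets_p_one(self):
        ds = make_dataset([[0, 0, 0, 0, 0, 0]], [0, 0, 0, 1, 1, 1], kind="snp")
        assert fisher_select(ds, 1) == ["v1"]
        from srcshave import fisher_pvalues
        assert fisher_pvalues(ds)[0] == 1.0

    def test_spot_tables_match_hypergeometric_oracle(self):
        for table in ([[3, 7], [8, 2]], [[1, 9], [4, 6]], [[6, 1], [2, 8]]):
            assert fisher_table_pvalue(np.array(table)) == pytest.approx(
                hypergeometric_two_sided(table), rel=1e-7)


class TestOverlapReport:
    def test_identical_lists(self):
        r = overlap_report(list(range(10)), list(range(10)), list(range(10)))
        assert r["abc"] == 10
        assert sum(v for k, v in r.items() if k != "abc") == 0

    def test_disjoint_lists(self):
        r = overlap_report([1, 2], [3, 4], [5, 6])
        assert r["ab"] == r["ac"] == r["bc"] == r["abc"] == 0
        assert r["a_only"] == r["b_only"] == r["c_only"] == 2

    def test_regions_partition_the_union(self):
        a, b, c = [1, 2, 3, 4], [3, 4, 5], [4, 5, 6, 7]
        r = overlap_report(a, b, c)
        assert sum(r.values()) == len(set(a) | set(b) | set(c))

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            overlap_report([1, 1], [2], [3])


def test_src_selection_beats_random_panels_in_loo(benchmark_runs):
    """Panels picked by SRC shaving should classify better than random ones."""
    wins = 0
    for seed, (planted, res) in benchmark_runs.items():
        expr, snp, gmap, truth = generate(benchmark_config(seed))
        gene_of = gmap.variable_to_gene()
        top_genes = set(res.ranked_genes[:10])
        selected = [v for v in expr.variable_ids if gene_of[v] in top_genes]
        rng = np.random.default_rng(seed + 100)
        rand = random_select(expr, len(selected), rng)
        cr_src = loo_cv(expr, selected).cr
        cr_rand = loo_cv(expr, rand).cr
        wins += cr_src >= cr_rand
    assert wins >= 4
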