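import numpy as np
import pandas as pd
import pytest

from tdratio import (ExpressionMatrix, GeneSetCollection, compare_group_activity,
                     enrichment_score, geometric_log2_fold_change, preranked_gsea,
                     random_set_enrichment_control, single_sample_activity)


def brute_force_es(scores, in_set, weight=1.0):
    """Independent running-sum implementation: explicit loop, no vectorization."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    hit_weight = sum(abs(scores[i]) ** weight for i in order if in_set[i])
    n_miss = len(scores) - sum(in_set)
    running, best = 0.0, 0.0
    for i in order:
        if in_set[i]:
            running += abs(scores[i]) ** weight / hit_weight
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def _matrix(values, genes=None, state="cpm"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cols = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), state)


class TestGeometricFoldChange:
    def test_identical_groups_zero(self, rng):
        vals = rng.gamma(2, 100, size=(20, 4))
        fc = geometric_log2_fold_change(_matrix(vals), _matrix(vals))
        np.testing.assert_allclose(fc, 0.0, atol=1e-12)

    def test_fourfold_change_is_two(self, rng):
        pri = rng.gamma(2, 100, size=(15, 3)) + 1
        fc = geometric_log2_fold_change(_matrix(pri), _matrix(4 * pri),
                                        pseudocount=0.0)
        np.testing.assert_allclose(fc, 2.0, atol=1e-12)

    def test_pseudocount_handles_zeros(self):
        pri = np.zeros((1, 2))
        met = np.full((1, 2), 3.0)
        fc = geometric_log2_fold_change(_matrix(pri), _matrix(met), pseudocount=1.0)
        assert fc.iloc[0] == pytest.approx(np.log2(4 / 1))

    def test_log_space_rejected(self, rng):
        m = _matrix(rng.normal(size=(5, 2)), state="log_space")
        with pytest.raises(ValueError, match="linear"):
            geometric_log2_fold_change(m, m)


class TestEnrichmentScore:
    def test_matches_brute_force_on_worked_example(self):
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0, -5.0])
        in_set = np.array([True, True, True] + [False] * 7)
        es = enrichment_score(scores, in_set)
        assert es == pytest.approx(brute_force_es(scores, in_set))
        assert es > 0

    def test_bottom_set_negative(self):
        scores = np.arange(10, 0, -1.0)
        in_set = np.zeros(10, dtype=bool)
        in_set[-2:] = True
        es = enrichment_score(scores, in_set)
        assert es == pytest.approx(brute_force_es(scores, in_set))
        assert es < 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = rng.normal(size=n)
        in_set = np.zeros(n, dtype=bool)
        in_set[rng.choice(n, 7, replace=False)] = True
        assert enrichment_score(scores, in_set) == \
            pytest.approx(brute_force_es(scores, in_set))

    def test_set_and_complement_have_opposite_signs(self, rng):
        scores = rng.normal(size=40)
        in_set = np.zeros(40, dtype=bool)
        in_set[rng.choice(40, 10, replace=False)] = True
        assert np.sign(enrichment_score(scores, in_set)) == \
            -np.sign(enrichment_score(scores, ~in_set))

    def test_full_or_empty_set_errors(self, rng):
        scores = rng.normal(size=10)
        with pytest.raises(ValueError):
            enrichment_score(scores, np.ones(10, dtype=bool))
        with pytest.raises(ValueError):
            enrichment_score(scores, np.zeros(10, dtype=bool))


class TestPrerankedGsea:
    @pytest.fixture
    def ranking(self, rng):
        genes = [f"G{i:03d}" for i in range(100)]
        return pd.Series(np.sort(rng.normal(size=100))[::-1], index=genes)

    def test_top_set_positive_bottom_negative(self, ranking):
        gs = GeneSetCollection({"top": list(ranking.index[:8]),
                                "bottom": list(ranking.index[-8:])})
        res = preranked_gsea(ranking, gs, n_perm=200, seed=0).set_index("gene_set")
        assert res.loc["top", "nes"] > 0
        assert res.loc["top", "direction"] == "metastatic"
        assert res.loc["bottom", "nes"] < 0
        assert res.loc["bottom", "direction"] == "primary"
        assert np.sign(res["nes"]).equals(np.sign(res["es"]))

    def test_p_lower_bound(self, ranking):
        gs = GeneSetCollection({"top": list(ranking.index[:10])})
        res = preranked_gsea(ranking, gs, n_perm=99, seed=1)
        assert res["p"].min() >= 0.01 - 1e-12

    def test_null_pvalues_roughly_uniform(self, rng):
        genes = [f"G{i:03d}" for i in range(150)]
        ranking = pd.Series(rng.normal(size=150), index=genes)
        sets = {f"r{i}": list(np.array(genes)[rng.choice(150, 12, replace=False)])
                for i in range(60)}
        res = preranked_gsea(ranking, GeneSetCollection(sets), n_perm=199, seed=2)
        from scipy.stats import kstest
        assert kstest(res["p"], "uniform").statistic < 0.2

    def test_unpruned_set_error(self, ranking):
        gs = GeneSetCollection({"alien": ["X1", "X2"]})
        with pytest.raises(ValueError, match="pruning"):
            preranked_gsea(ranking, gs, n_perm=10, seed=0)


class TestSingleSampleActivity:
    def test_ordering_between_samples(self):
        # set genes top-ranked in sample 0, bottom-ranked in sample 1
        vals = np.column_stack([np.arange(20, 0, -1.0), np.arange(1.0, 21)])
        m = _matrix(vals)
        gs = GeneSetCollection({"S": [f"G{i}" for i in range(5)]})
        act = single_sample_activity(m, gs).set_index("sample_id")
        assert act.loc["s0", "score"] > act.loc["s1", "score"]

    def test_monotone_transform_invariance(self, rng):
        vals = rng.gamma(2, 100, size=(30, 5))
        gs = GeneSetCollection({"S": [f"G{i}" for i in range(8)]})
        a = single_sample_activity(_matrix(vals), gs)["score"]
        b = single_sample_activity(_matrix(np.exp(vals / 50)), gs)["score"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_matches_brute_force_ecdf_difference(self, rng):
        n, tau = 20, 0.25
        vals = rng.gamma(2, 100, size=(n, 1))
        set_genes = [f"G{i}" for i in [0, 3, 7, 11]]
        m = _matrix(vals)
        score = single_sample_activity(m, GeneSetCollection({"S": set_genes}),
                                       tau=tau)["score"][0]
        # independent oracle: explicit ECDF walk down the sample's ranking
        order = np.argsort(-vals[:, 0])
        in_set = np.isin(np.arange(n), [0, 3, 7, 11])[order]
        rank_vals = np.arange(n, 0, -1) ** tau
        p_in = p_out = total = 0.0
        w_sum = rank_vals[in_set].sum()
        for i in range(n):
            if in_set[i]:
                p_in += rank_vals[i] / w_sum
            else:
                p_out += 1.0 / (n - in_set.sum())
            total += p_in - p_out
        assert score == pytest.approx(total / n)

    def test_missing_set_error(self, rng):
        m = _matrix(rng.gamma(2, 100, size=(5, 2)))
        with pytest.raises(ValueError, match="no genes"):
            single_sample_activity(m, GeneSetCollection({"S": ["X9"]}))


class TestCompareGroupActivity:
    def _scores(self, rng, shift=0.0, n=20):
        rows = []
        for j in range(2 * n):
            group_shift = shift if j >= n else 0.0
            rows.append({"sample_id": f"s{j}", "gene_set": "S",
                         "score": rng.normal(group_shift, 1.0)})
        groups = {f"s{j}": ("met" if j >= n else "pri") for j in range(2 * n)}
        return pd.DataFrame(rows), groups

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        scores, groups = self._scores(rng, shift=0.0)
        res = compare_group_activity(scores, groups)
        assert res["p"][0] >= 0.05

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        scores, groups = self._scores(rng, shift=2.0)
        res = compare_group_activity(scores, groups)
        assert res["fdr"][0] < 0.1

    def test_small_group_error(self, rng):
        scores = pd.DataFrame({"sample_id": ["a", "b", "c", "d"],
                               "gene_set": "S",
                               "score": rng.normal(size=4)})
        groups = {"a": "x", "b": "x", "c": "x", "d": "y"}
        with pytest.raises(ValueError, match=">= 3"):
            compare_group_activity(scores, groups)


class TestRandomSetControl:
    def test_null_cohort_shows_no_selective_enrichment(self, rng):
        # ranking from a genuinely null cohort: both groups drawn from the
        # same distribution, so fold changes carry no set structure
        vals = rng.gamma(2.0, 100.0, size=(300, 24))
        ranking = geometric_log2_fold_change(_matrix(vals[:, :12]),
                                             _matrix(vals[:, 12:]))
        out = random_set_enrichment_control(ranking, sizes=[10, 20, 30],
                                            n_sets=500, seed=7, n_perm=99)
        assert out["significant_fraction"][0] <= 0.1
        split = out["positive_fraction"][0]
        sd = np.sqrt(0.25 / 500)
        assert abs(split - 0.5) < 3 * sd + 1e-9

    def test_single_set_summary(self, rng):
        ranking = pd.Series(rng.normal(size=50),
                            index=[f"G{i}" for i in range(50)])
        out = random_set_enrichment_control(ranking, sizes=[5], n_sets=1,
                                            seed=0, n_perm=20)
        assert len(out) == 1
        assert out["n_sets"][0] == 1

    def test_seed_reproducibility(self, rng):
        ranking = pd.Series(rng.normal(size=80),
                            index=[f"G{i}" for i in range(80)])
        a = random_set_enrichment_control(ranking, sizes=[8], n_sets=20,
                                          seed=3, n_perm=50)
        b = random_set_enrichment_control(ranking, sizes=[8], n_sets=20,
                                          seed=3, n_perm=50)
        pd.testing.assert_frame_equal(a, b)
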