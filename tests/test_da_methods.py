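import sys

import numpy as np
import pytest
from scipy import stats

from dabench.counts_io import CountMatrix, GroupDesign
from dabench.da_methods import (
    METHODS,
    MethodResult,
    binomial_pooled_test,
    fisher_pooled_test,
    overdispersed_glm_test,
    poisson_glm_test,
    run_external_method,
    transformed_t_test,
    wmw_test,
)

# ---------------------------------------------------------------------------
# independent oracles


def fisher_minlike_oracle(a, b, t1, t2):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    k = a + b  # pooled gene fragments
    lo, hi = max(0, k - t2), min(k, t1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, t1 + t2, k, t1)
    observed = pmf[support == a][0]
    return min(1.0, pmf[pmf <= observed * (1 + 1e-7)].sum())


def binom_minlike_oracle(x, n, p0):
    """Two-sided binomial p by exhaustive enumeration."""
    support = np.arange(n + 1)
    pmf = stats.binom.pmf(support, n, p0)
    observed = pmf[x]
    return min(1.0, pmf[pmf <= observed * (1 + 1e-7)].sum())


def wmw_exact_oracle(x, y):
    """Two-sided WMW p by enumerating all group assignments."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    m1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:m1].sum() - m1 * (m1 + 1) / 2
    center = m1 * len(y) / 2
    count = total = 0
    for comb in combinations(range(len(pooled)), m1):
        u = ranks[list(comb)].sum() - m1 * (m1 + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            count += 1
    return count / total


def equal_total_matrix(gene_values, filler_to=None):
    """Single test gene + filler row giving every column the same total."""
    vals = np.asarray(gene_values)
    total = filler_to or (vals.max() * 2)
    filler = total - vals
    return CountMatrix(("target", "filler"), tuple(f"s{i}" for i in range(vals.size)),
                       np.vstack([vals, filler]))


# ---------------------------------------------------------------------------


class TestMethodResult:
    def test_rejects_out_of_range_p(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            MethodResult("m", ("g1",), np.array([1.5]))

    def test_missing_p_allowed(self):
        r = MethodResult("m", ("g1", "g2"), np.array([np.nan, 0.5]))
        assert r.n_missing == 1


class TestPoissonGLM:
    def test_identical_normalized_counts_give_null(self, design6):
        m = equal_total_matrix([10, 10, 10, 10, 10, 10], filler_to=100)
        res = poisson_glm_test(m, design6)
        assert res.log2_fold_change[0] == pytest.approx(0.0)
        assert res.p_value[0] == pytest.approx(1.0)

    def test_rate_ratio_recovered_exactly(self, design6):
        # group means in ratio 5 at equal depths -> MLE fold-change is 5
        m = equal_total_matrix([100, 100, 100, 500, 500, 500], filler_to=1000)
        res = poisson_glm_test(m, design6)
        assert res.log2_fold_change[0] == pytest.approx(np.log2(5.0))

    def test_zero_group_gives_missing_p(self, design6):
        m = equal_total_matrix([0, 0, 0, 5, 6, 7], filler_to=50)
        res = poisson_glm_test(m, design6)
        assert np.isnan(res.p_value[0])

    def test_matches_statsmodels_glm(self, design6):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 80, size=(10, 6))
        matrix = CountMatrix(
            tuple(f"g{i}" for i in range(10)), design6.sample_ids, counts
        )
        x = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        offset = np.log(matrix.column_totals)
        res = poisson_glm_test(matrix, design6)
        res_o = overdispersed_glm_test(matrix, design6)
        for i in range(10):
            fit = sm.GLM(
                counts[i], x, family=sm.families.Poisson(), offset=offset
            ).fit(tol=1e-12)
            beta = fit.params[1]
            assert res.log2_fold_change[i] == pytest.approx(beta / np.log(2), rel=1e-6)
            assert res.p_value[i] == pytest.approx(fit.pvalues[1], rel=1e-5)
            qfit = sm.GLM(
                counts[i], x, family=sm.families.Poisson(), offset=offset
            ).fit(scale="X2", tol=1e-12)
            t = qfit.params[1] / qfit.bse[1]
            p_q = 2 * stats.t.sf(abs(t), df=4)
            assert res_o.p_value[i] == pytest.approx(p_q, rel=1e-5)

    def test_lrt_option(self, design6):
        m = equal_total_matrix([5, 9, 7, 20, 25, 22], filler_to=60)
        wald = poisson_glm_test(m, design6)
        lrt = poisson_glm_test(m, design6, inference="lrt")
        # both reject strongly, but are distinct statistics
        assert lrt.p_value[0] < 0.01 and wald.p_value[0] < 0.01
        assert lrt.p_value[0] != wald.p_value[0]


class TestOGLM:
    def test_needs_residual_df(self):
        m = equal_total_matrix([3, 7], filler_to=20)
        d = GroupDesign(m.sample_ids, ("A", "B"))
        with pytest.raises(ValueError, match="m - 2"):
            overdispersed_glm_test(m, d)

    def test_dispersion_near_one_for_poisson_data(self, design6):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(400, 6))
        matrix = CountMatrix(
            tuple(f"g{i}" for i in range(400)), design6.sample_ids, counts
        )
        from dabench.da_methods import _glm_core

        _, _, pearson, _, _ = _glm_core(matrix, design6)
        assert np.median(pearson / 4) == pytest.approx(
            stats.chi2.median(4) / 4, rel=0.15
        )

    def test_floor_dispersion_never_more_liberal(self, design6):
        rng = np.random.default_rng(1)
        counts = rng.poisson(30, size=(100, 6))
        matrix = CountMatrix(
            tuple(f"g{i}" for i in range(100)), design6.sample_ids, counts
        )
        plain = overdispersed_glm_test(matrix, design6)
        floored = overdispersed_glm_test(matrix, design6, floor_dispersion=True)
        assert (floored.p_value >= plain.p_value - 1e-12).all()


class TestExactTests:
    def test_fisher_symmetric_table_gives_one(self, design6):
        m = equal_total_matrix([5, 5, 5, 5, 5, 5], filler_to=50)
        assert fisher_pooled_test(m, design6).p_value[0] == pytest.approx(1.0)

    def test_fisher_matches_enumeration_oracle(self):
        expected = fisher_minlike_oracle(10, 2, 1000, 1000)
        assert stats.fisher_exact([[10, 990], [2, 998]]).pvalue == pytest.approx(
            expected, rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_fisher_random_small_instances(self, seed, design6):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 6, size=6)  # pooled counts <= 30
        vals[0] += 1
        m = equal_total_matrix(vals, filler_to=40)
        res = fisher_pooled_test(m, design6)
        x1, x2 = int(vals[:3].sum()), int(vals[3:].sum())
        assert res.p_value[0] == pytest.approx(
            fisher_minlike_oracle(x1, x2, 120, 120), rel=1e-7
        )

    def test_fisher_group_swap_invariance(self, design6):
        m = equal_total_matrix([9, 1, 4, 0, 2, 1], filler_to=30)
        p1 = fisher_pooled_test(m, design6).p_value[0]
        p2 = fisher_pooled_test(m, design6.swapped()).p_value[0]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_binomial_balanced_example(self, design6):
        # x = (8, 2) with equal pooled depths: Binomial(10, 0.5) enumeration
        m = equal_total_matrix([4, 3, 1, 1, 1, 0], filler_to=50)
        res = binomial_pooled_test(m, design6)
        assert res.p_value[0] == pytest.approx(binom_minlike_oracle(8, 10, 0.5))
        assert res.p_value[0] == pytest.approx(0.109375)

    @pytest.mark.parametrize("seed", range(8))
    def test_binomial_random_small_instances(self, seed, design6):
        rng = np.random.default_rng(100 + seed)
        vals = rng.integers(0, 6, size=6)
        vals[1] += 1
        m = equal_total_matrix(vals, filler_to=40)
        res = binomial_pooled_test(m, design6)
        x1, x2 = int(vals[:3].sum()), int(vals[3:].sum())
        assert res.p_value[0] == pytest.approx(
            binom_minlike_oracle(x1, x1 + x2, 0.5), rel=1e-9
        )

    def test_binomial_zero_pooled_counts_give_one(self, design6):
        m = equal_total_matrix([0, 0, 0, 0, 0, 0], filler_to=10)
        assert binomial_pooled_test(m, design6).p_value[0] == 1.0

    def test_binomial_null_consistent_observation(self, design6):
        # x1 = x2 with equal depths: the modal outcome -> p = 1
        m = equal_total_matrix([2, 2, 1, 2, 2, 1], filler_to=20)
        assert binomial_pooled_test(m, design6).p_value[0] == pytest.approx(1.0)


class TestTTest:
    def test_identical_groups_give_p_one(self, design6):
        m = equal_total_matrix([1, 2, 3, 1, 2, 3], filler_to=10)
        res = transformed_t_test(m, design6)
        assert res.statistic[0] == pytest.approx(0.0)
        assert res.p_value[0] == pytest.approx(1.0)

    def test_textbook_pooled_t(self, small_matrix, design6):
        # gene gA is {1,2,3} vs {4,5,6} at equal depths: t = 3/sqrt(2/3), df=4
        res = transformed_t_test(small_matrix, design6, "identity", "pooled")
        t_expected = 3.0 / np.sqrt(2.0 / 3.0)
        assert res.statistic[0] == pytest.approx(t_expected)
        assert res.p_value[0] == pytest.approx(2 * stats.t.sf(t_expected, 4))

    def test_zero_variance_both_groups_missing(self, design6):
        # both groups constant (whether or not the means differ) -> undefined
        counts = np.array([[5, 5, 5, 9, 9, 9], [7, 7, 7, 7, 7, 7]])
        m2 = CountMatrix(("c1", "c2"), tuple(f"s{i}" for i in range(6)), counts)
        res2 = transformed_t_test(m2, design6)
        assert np.isnan(res2.p_value).all()
        # ordinary within-group variance keeps the statistic defined
        m = equal_total_matrix([5, 6, 5, 9, 10, 9], filler_to=20)
        res = transformed_t_test(m, design6)
        assert not np.isnan(res.p_value[0])

    @pytest.mark.parametrize("transform", ["identity", "sqrt", "log1p"])
    def test_welch_vs_pooled_differ_under_unequal_variance(self, design6, transform):
        m = equal_total_matrix([1, 2, 3, 10, 40, 90], filler_to=100)
        pooled = transformed_t_test(m, design6, transform, "pooled")
        welch = transformed_t_test(m, design6, transform, "welch")
        assert pooled.p_value[0] != welch.p_value[0]

    def test_log1p_fold_change_is_log2_scale_difference(self, design6):
        m = equal_total_matrix([1, 1, 1, 3, 3, 3], filler_to=10)
        res = transformed_t_test(m, design6, "log1p")
        assert res.log2_fold_change[0] == pytest.approx(np.log2(4) - np.log2(2))


class TestWMW:
    def test_separated_groups_exact_p(self, small_matrix, design6):
        # {1,2,3} vs {4,5,6}: 2 extreme assignments x 2 tails / C(6,3)=20
        res = wmw_test(small_matrix, design6)
        assert res.p_value[0] == pytest.approx(0.1)

    def test_all_identical_gives_one(self, design6):
        counts = np.array([[5, 5, 5, 5, 5, 5], [7, 7, 7, 7, 7, 7]])
        m = CountMatrix(("c1", "c2"), tuple(f"s{i}" for i in range(6)), counts)
        res = wmw_test(m, design6)
        assert (res.p_value == 1.0).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1, 9)) * 3  # distinct values, m1=m2=4
        m = equal_total_matrix(vals, filler_to=30)
        d = GroupDesign(m.sample_ids, ("A",) * 4 + ("B",) * 4)
        res = wmw_test(m, d)
        assert res.p_value[0] == pytest.approx(
            wmw_exact_oracle(vals[:4].astype(float), vals[4:].astype(float)), rel=1e-9
        )


class TestSymmetry:
    """Every method: group relabeling keeps p and negates the fold-change."""

    @pytest.fixture
    def random_matrix(self):
        rng = np.random.default_rng(31)
        counts = rng.integers(0, 60, size=(15, 8))
        counts[0] += 1
        return CountMatrix(
            tuple(f"g{i}" for i in range(15)),
            tuple(f"s{j}" for j in range(8)),
            counts,
        )

    @pytest.mark.parametrize("name", sorted(METHODS))
    def test_group_swap(self, random_matrix, name):
        d = GroupDesign(random_matrix.sample_ids, ("A",) * 4 + ("B",) * 4)
        r1 = METHODS[name](random_matrix, d)
        r2 = METHODS[name](random_matrix, d.swapped())
        np.testing.assert_allclose(r1.p_value, r2.p_value, rtol=1e-9, equal_nan=True)
        if name != "wmw":  # U statistic orientation differs; p is what matters
            finite = ~np.isnan(r1.log2_fold_change) & ~np.isnan(r2.log2_fold_change)
            np.testing.assert_allclose(
                r1.log2_fold_change[finite], -r2.log2_fold_change[finite], rtol=1e-9
            )


class TestExternalAdapter:
    def _adapter(self, tmp_path, body):
        script = tmp_path / "adapter.py"
        script.write_text(
            "import argparse, csv\n"
            "ap = argparse.ArgumentParser()\n"
            "for a in ('--counts', '--design', '--out'): ap.add_argument(a)\n"
            "args = ap.parse_args()\n"
            "genes = [l.split('\\t')[0] for l in open(args.counts).read().splitlines()[1:]]\n"
            + body
        )
        return [sys.executable, str(script)]

    def test_constant_p_adapter(self, tmp_path, small_matrix, design6):
        adapter = self._adapter(
            tmp_path,
            "with open(args.out, 'w') as fh:\n"
            "    fh.write('gene_id\\tp_value\\tlog2_fold_change\\n')\n"
            "    for g in genes: fh.write(f'{g}\\t0.5\\tNA\\n')\n",
        )
        res = run_external_method(small_matrix, design6, adapter, name="mock")
        assert res.method_name == "mock"
        assert (res.p_value == 0.5).all()
        assert np.isnan(res.log2_fold_change).all()

    def test_missing_gene_rejected(self, tmp_path, small_matrix, design6):
        adapter = self._adapter(
            tmp_path,
            "with open(args.out, 'w') as fh:\n"
            "    fh.write('gene_id\\tp_value\\tlog2_fold_change\\n')\n"
            "    for g in genes[1:]: fh.write(f'{g}\\t0.5\\t0\\n')\n",
        )
        with pytest.raises(RuntimeError, match="missing gene"):
            run_external_method(small_matrix, design6, adapter)

    def test_invalid_p_rejected(self, tmp_path, small_matrix, design6):
        adapter = self._adapter(
            tmp_path,
            "with open(args.out, 'w') as fh:\n"
            "    fh.write('gene_id\\tp_value\\tlog2_fold_change\\n')\n"
            "    for g in genes: fh.write(f'{g}\\t1.5\\t0\\n')\n",
        )
        with pytest.raises(RuntimeError, match="outside"):
            run_external_method(small_matrix, design6, adapter)

    def test_missing_executable(self, small_matrix, design6):
        with pytest.raises(RuntimeError, match="not found"):
            run_external_method(small_matrix, design6, "/no/such/binary")
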