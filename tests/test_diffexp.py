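"""Differential expression: PCA outliers, size factors, dispersions,
the NB exact test against independent oracles, BH-FDR, and summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest

from srnakit.diffexp import (
    SmallRNADEModel,
    bh_fdr,
    boxplot_table,
    cluster_samples_newick,
    estimate_dispersions,
    ma_table,
    nb_exact_test,
    pca_outliers,
    significance_stars,
    size_factors,
)


# ---------------------------------------------------------------------------
# Independent oracle: full enumeration with lgamma-based pmfs (no scipy,
# no code shared with the implementation).
# ---------------------------------------------------------------------------

def _pmf(k: int, mean: float, var: float) -> float:
    if var <= mean * (1 + 1e-12):  # Poisson limit
        return math.exp(-mean + k * math.log(mean) - math.lgamma(k + 1)) if mean > 0 else float(k == 0)
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return math.exp(
        math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
        + r * math.log(p) + k * math.log(1 - p)
    )


def oracle_exact_p(KA, KB, sA, sB, alpha):
    KS = KA + KB
    if KS == 0:
        return 1.0
    SA, SB = sum(sA), sum(sB)
    S2A, S2B = sum(x * x for x in sA), sum(x * x for x in sB)
    mu = KS / (SA + SB)
    mA, vA = mu * SA, mu * SA + alpha * mu * mu * S2A
    mB, vB = mu * SB, mu * SB + alpha * mu * mu * S2B
    probs = [_pmf(a, mA, vA) * _pmf(KS - a, mB, vB) for a in range(KS + 1)]
    obs = probs[KA]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-8)) / sum(probs))


def _series(countsA, countsB, sA, sB):
    libs = [f"A{i}" for i in range(len(countsA))] + [f"B{i}" for i in range(len(countsB))]
    counts = pd.Series(list(countsA) + list(countsB), index=libs, dtype=float)
    s = pd.Series(list(sA) + list(sB), index=libs, dtype=float)
    groups = {lib: lib[0] for lib in libs}
    return counts, s, groups


class TestNBExactTest:
    def test_symmetric_split_is_p1(self):
        counts, s, groups = _series([5, 5], [5, 5], [1, 1], [1, 1])
        assert nb_exact_test(counts, s, groups, 0.1) == pytest.approx(1.0)

    def test_zero_total_is_p1(self):
        counts, s, groups = _series([0, 0], [0, 0], [1, 1], [1, 1])
        assert nb_exact_test(counts, s, groups, 0.1) == 1.0

    def test_poisson_limit_matches_binomial(self):
        # alpha -> 0: conditional on the total, K_A is binomial
        for KA, KB in [(3, 17), (10, 10), (0, 25), (30, 20)]:
            counts, s, groups = _series([KA], [KB], [1.0], [1.0])
            p = nb_exact_test(counts, s, groups, 0.0)
            pb = binomtest(KA, KA + KB, 0.5).pvalue
            assert p == pytest.approx(pb, abs=1e-6)

    def test_poisson_limit_unequal_sizes(self):
        counts, s, groups = _series([12], [3], [2.0], [1.0])
        p = nb_exact_test(counts, s, groups, 0.0)
        pb = binomtest(12, 15, 2.0 / 3.0).pvalue
        assert p == pytest.approx(pb, abs=1e-6)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            nA, nB = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            sA = rng.uniform(0.5, 2.0, nA).round(3)
            sB = rng.uniform(0.5, 2.0, nB).round(3)
            KS = int(rng.integers(1, 201))
            KA = int(rng.integers(0, KS + 1))
            alpha = float(rng.choice([0.0, 0.01, 0.1, 0.5]))
            # spread the group totals over libraries arbitrarily
            cA = rng.multinomial(KA, np.ones(nA) / nA)
            cB = rng.multinomial(KS - KA, np.ones(nB) / nB)
            counts, s, groups = _series(cA, cB, sA, sB)
            got = nb_exact_test(counts, s, groups, alpha)
            want = oracle_exact_p(KA, KS - KA, list(sA), list(sB), alpha)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_more_extreme_split_smaller_p(self):
        ps = []
        for KA in (10, 5, 1):
            counts, s, groups = _series([KA], [20 - KA], [1.0], [1.0])
            ps.append(nb_exact_test(counts, s, groups, 0.05))
        assert ps[0] > ps[1] > ps[2]


class TestSizeFactors:
    def test_identical_libraries_unity(self):
        counts = pd.DataFrame({"A": [3.0, 9.0], "B": [3.0, 9.0]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_scaled_library_ratio(self):
        a = np.array([5.0, 10.0, 20.0, 40.0, 80.0])
        counts = pd.DataFrame({"A": a, "B": 3 * a})
        s = size_factors(counts)
        assert s["B"] / s["A"] == pytest.approx(3.0)

    def test_single_feature(self):
        counts = pd.DataFrame({"A": [4.0], "B": [8.0]})
        s = size_factors(counts)
        assert s["B"] / s["A"] == pytest.approx(2.0)

    def test_no_common_feature_errors(self):
        counts = pd.DataFrame({"A": [4.0, 0.0], "B": [0.0, 8.0]})
        with pytest.raises(ValueError, match="size factors"):
            size_factors(counts)


class TestDispersions:
    def _groups(self, n):
        libs = [f"N{i}" for i in range(n)] + [f"C{i}" for i in range(n)]
        return libs, {lib: lib[0] for lib in libs}

    def test_poisson_counts_small_alpha(self):
        rng = np.random.default_rng(4)
        libs, groups = self._groups(9)
        mu = rng.uniform(50, 500, size=1000)
        counts = pd.DataFrame(rng.poisson(mu[:, None], size=(1000, 18)),
                              index=[f"f{i}" for i in range(1000)], columns=libs)
        s = pd.Series(1.0, index=libs)
        model = estimate_dispersions(counts, s, groups)
        assert float(np.median(model.final)) <= 0.05

    def test_nb_counts_recover_alpha(self):
        rng = np.random.default_rng(5)
        libs, groups = self._groups(9)
        alpha = 0.2
        mu = rng.uniform(50, 500, size=1000)
        r = 1 / alpha
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(1000, 18)),
            index=[f"f{i}" for i in range(1000)], columns=libs)
        model = estimate_dispersions(counts, pd.Series(1.0, index=libs), groups)
        assert 0.1 <= float(np.median(model.final)) <= 0.4

    def test_constant_counts_fall_back_to_trend(self):
        libs, groups = self._groups(3)
        counts = pd.DataFrame(
            {lib: [100.0, 50.0, 10.0, 200.0] for lib in libs},
            index=list("abcd"))
        model = estimate_dispersions(counts, pd.Series(1.0, index=libs), groups)
        assert np.allclose(model.raw, 0.0)
        assert np.allclose(model.final, model.trend(model.base_mean))

    def test_single_replicate_group_rejected(self):
        counts = pd.DataFrame({"N1": [1.0], "N2": [2.0], "C1": [3.0]})
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(counts, pd.Series(1.0, index=counts.columns),
                                 {"N1": "N", "N2": "N", "C1": "C"})


class TestBHFDR:
    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_hand_computed_stepup(self):
        # q_(i) = min_{j>=i} p_(j) * m / j -> all 0.04 for this ladder
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_and_permutation_invariant(self, ps):
        q = np.asarray(bh_fdr(ps))
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p
        perm = np.random.default_rng(0).permutation(len(ps))
        q2 = np.asarray(bh_fdr(list(np.asarray(ps)[perm])))
        assert np.allclose(np.sort(q), np.sort(q2))


class TestPCAOutliers:
    def _nev(self, X, samples):
        return pd.DataFrame(X.T, columns=samples,
                            index=[f"f{i}" for i in range(X.shape[1])])

    def test_displaced_sample_flagged(self):
        # 18 clustered samples plus one displaced far along a fixed axis;
        # the 4-SD criterion on PC1 is verified by direct computation
        rng = np.random.default_rng(6)
        n, p = 19, 40
        X = rng.normal(0, 1, size=(n, p))
        direction = np.zeros(p)
        direction[0] = 1.0
        X[-1] += 60 * direction
        samples = [f"S{i}" for i in range(n)]
        nev = self._nev(np.power(2.0, X) - 1 + 20, samples)  # undone by log2(x+1)
        rep = pca_outliers(nev, outlier_sd=4.0, log_transform=True)
        # direct check of the criterion from the reported scores
        z = (rep.scores - rep.scores.mean()).abs() / rep.scores.std(ddof=0)
        assert (z.loc["S18"] >= 4.0).any()
        assert rep.flagged == ["S18"]

    def test_identical_samples_degenerate(self):
        nev = pd.DataFrame(5.0, index=[f"f{i}" for i in range(10)],
                           columns=[f"S{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="degenerate"):
            rep = pca_outliers(nev, 4.0)
        assert rep.flagged == [] and rep.degenerate

    def test_partner_removed_with_flagged(self):
        rng = np.random.default_rng(7)
        n = 20
        X = rng.normal(0, 0.5, size=(n, 30))
        X[4] += 50  # library N5
        samples = [f"N{i}" for i in range(1, 11)] + [f"C{i}" for i in range(1, 11)]
        pairs = {s: s[1:] for s in samples}
        nev = self._nev(np.power(2.0, X) - 1 + 10, samples)
        rep = pca_outliers(nev, 4.0, pairs=pairs)
        assert rep.flagged == ["N5"]
        assert rep.removed == ["C5", "N5"]

    def test_too_few_samples_rejected(self):
        nev = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match=">= 4"):
            pca_outliers(nev, 4.0)


class TestModelAndSummaries:
    def _fit(self):
        rng = np.random.default_rng(8)
        libs = [f"N{i}" for i in range(1, 6)] + [f"C{i}" for i in range(1, 6)]
        mu = rng.uniform(50, 300, size=60)
        counts = rng.poisson(mu[:, None], size=(60, 10)).astype(float)
        counts[:5, 5:] *= 8  # five strongly upregulated features
        df = pd.DataFrame(counts, index=[f"f{i}" for i in range(60)], columns=libs)
        model = SmallRNADEModel.from_dataframe(df)
        return model.fit(de_fdr=0.1)

    def test_spiked_features_significant_up(self):
        res = self._fit()
        assert set(res.table.iloc[:5].query("direction == 'up'").index) == {
            "f0", "f1", "f2", "f3", "f4"
        }

    def test_direction_ns_iff_fdr_above_threshold(self):
        res = self._fit()
        ns = res.table["direction"] == "ns"
        assert (res.table.loc[ns, "fdr"] >= 0.1).all()
        assert (res.table.loc[~ns, "fdr"] < 0.1).all()

    def test_summary_mentions_counts(self):
        res = self._fit()
        text = res.summary()
        assert "significant" in text and "upregulated" in text

    def test_ma_flag_matches_fdr(self):
        res = self._fit()
        ma = res.ma_table()
        assert (ma["significant"] == (res.table["fdr"] < 0.1)).all()

    def test_stars(self):
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""

    def test_identical_samples_join_at_zero(self):
        nev = pd.DataFrame(
            {"A": [1.0, 5.0, 9.0], "B": [1.0, 5.0, 9.0], "C": [9.0, 1.0, 2.0]},
            index=["f1", "f2", "f3"])
        nwk = cluster_samples_newick(nev, ["f1", "f2", "f3"])
        assert nwk is not None and "(A:0,B:0)" in nwk

    def test_clustering_skipped_without_features(self):
        nev = pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["f1"])
        with pytest.warns(UserWarning, match="skipped"):
            assert cluster_samples_newick(nev, ["f1"]) is None

    def test_boxplot_rows_and_stars(self):
        res = self._fit()
        bt = res.boxplot_table()
        n_sig = int((res.table["fdr"] < 0.1).sum())
        assert len(bt) == 2 * n_sig  # one row per group per significant feature
        assert set(bt["group"]) == {"N", "C"}
        assert (bt["q1"] <= bt["median"]).all() and (bt["median"] <= bt["q3"]).all()
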