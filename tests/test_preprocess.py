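"""Filtering rules, kNN imputation and the rank-normal transform."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, rankdata, spearmanr

from methclock.methyl_io import MethylationDataset
from methclock.preprocess import (filter_sites, impute_knn,
                                  rank_normal_per_sample, rank_normal_vector)


def _dataset(meth, total, ages=None):
    meth = np.asarray(meth)
    total = np.asarray(total)
    m, n = meth.shape
    sites = pd.DataFrame({"chrom": ["chr1"] * m, "pos": np.arange(1, m + 1) * 2})
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "individual_id": [f"i{i}" for i in range(n)],
            "sex": ["F"] * n,
            "age_years": ages if ages is not None else np.linspace(1, 50, n),
        }
    )
    return MethylationDataset(sites=sites, samples=samples,
                              meth=meth.astype(np.int64),
                              total=total.astype(np.int64))


def brute_force_filter(dataset, min_mean_cov=5.0, bounds=(0.1, 0.9),
                       max_missing=0.05):
    """Three-rule oracle, written from first principles per site."""
    keep = []
    for j in range(dataset.n_sites):
        tot = dataset.total[j]
        meth = dataset.meth[j]
        mean_cov = sum(tot) / len(tot)
        obs = tot > 0
        if obs.sum():
            ratios = [m / t for m, t in zip(meth[obs], tot[obs])]
            mean_ratio = sum(ratios) / len(ratios)
        else:
            mean_ratio = float("nan")
        missing_frac = 1 - obs.sum() / len(tot)
        ok = (
            mean_cov >= min_mean_cov
            and not np.isnan(mean_ratio)
            and bounds[0] <= mean_ratio <= bounds[1]
            and missing_frac < max_missing
        )
        keep.append(ok)
    return np.array(keep)


class TestFilterSites:
    def test_coverage_boundary(self):
        # mean coverage 4.9 is below the 5x rule
        total = np.full((2, 10), 10)
        total[0] = [4, 5, 5, 5, 5, 5, 5, 5, 5, 5]  # mean 4.9
        meth = (total * 0.5).astype(int)
        filtered, rep = filter_sites(_dataset(meth, total))
        assert filtered.n_sites == 1
        assert rep.n_fail_coverage == 1

    def test_constitutive_hypermethylation_excluded(self):
        total = np.full((2, 10), 20)
        meth = np.full((2, 10), 19)  # ratio 0.95
        meth[1] = 10  # ratio 0.5 -> retained
        filtered, rep = filter_sites(_dataset(meth, total))
        assert filtered.n_sites == 1
        assert rep.n_fail_meanmeth == 1

    def test_missing_boundary_is_exclusion(self):
        # missing in exactly 1 of 20 samples (5%) with max 0.05 -> excluded
        total = np.full((1, 20), 20)
        total[0, 3] = 0
        meth = (total * 0.5).astype(int)
        filtered, rep = filter_sites(_dataset(meth, total),
                                     max_missing_frac=0.05)
        assert filtered.n_sites == 0
        assert rep.n_fail_missing == 1

    def test_matches_brute_force_oracle_with_planted_violations(self, rng):
        m, n = 1000, 20
        total = rng.poisson(20, size=(m, n)) + 1
        p = rng.uniform(0.2, 0.8, size=m)
        # plant violations of each rule
        low_cov = rng.choice(m, 60, replace=False)
        total[low_cov] = rng.integers(0, 5, size=(60, n))
        hyper = rng.choice(np.setdiff1d(np.arange(m), low_cov), 50, False)
        p[hyper] = 0.97
        hypo = rng.choice(np.setdiff1d(np.arange(m), np.r_[low_cov, hyper]),
                          50, False)
        p[hypo] = 0.03
        missing = rng.choice(m, 80, replace=False)
        for j in missing:
            total[j, rng.choice(n, rng.integers(1, 4), replace=False)] = 0
        meth = rng.binomial(total, p[:, None])
        ds = _dataset(meth, total)
        filtered, rep = filter_sites(ds)
        expected = brute_force_filter(ds)
        got = pd.MultiIndex.from_frame(ds.sites).isin(
            pd.MultiIndex.from_frame(filtered.sites)
        )
        assert (got == expected).all()
        assert rep.n_retained == expected.sum()

    def test_idempotent(self, small_cohort):
        once, _ = filter_sites(small_cohort["dataset"])
        twice, rep = filter_sites(once)
        assert twice.n_sites == once.n_sites
        assert rep.n_fail_coverage == rep.n_fail_meanmeth == rep.n_fail_missing == 0

    def test_individual_missing_unit(self):
        # two samples of one individual: a site missing in either sample is
        # missing for that individual
        total = np.full((1, 4), 20)
        total[0, 1] = 0
        meth = (total * 0.5).astype(int)
        ds = _dataset(meth, total)
        ds.samples["individual_id"] = ["i0", "i0", "i1", "i2"]
        _, rep_sample = filter_sites(ds, max_missing_frac=0.3,
                                     missing_unit="sample")
        _, rep_ind = filter_sites(ds, max_missing_frac=0.3,
                                  missing_unit="individual")
        assert rep_sample.n_retained == 1  # 1/4 samples missing: 25% < 30%
        assert rep_ind.n_retained == 0  # 1/3 individuals missing: 33% >= 30%


class TestImputeKnn:
    def test_no_missing_identity(self, rng):
        X = rng.uniform(size=(30, 8))
        out = impute_knn(X, k=5)
        np.testing.assert_array_equal(out, X)

    def test_duplicate_sites_degenerate_neighbours(self):
        row = np.linspace(0.1, 0.9, 6)
        X = np.vstack([row, row, row])
        X[0, 2] = np.nan
        out = impute_knn(X, k=2)
        assert out[0, 2] == pytest.approx(row[2], abs=1e-12)

    def test_observed_entries_untouched(self, rng):
        X = rng.uniform(size=(60, 12))
        mask = rng.random(X.shape) < 0.05
        Xm = X.copy()
        Xm[mask] = np.nan
        out = impute_knn(Xm, k=5)
        np.testing.assert_array_equal(out[~mask], X[~mask])
        assert not np.isnan(out).any()

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError, match="k"):
            impute_knn(rng.uniform(size=(5, 4)), k=5)

    def test_heavy_missing_row_uses_row_mean(self):
        X = np.vstack([np.linspace(0, 1, 10) for _ in range(5)])
        X[0, :6] = np.nan  # 60% missing -> row-mean fallback
        out = impute_knn(X, k=2)
        expected = np.nanmean(X[0])
        np.testing.assert_allclose(out[0, :6], expected)

    def test_matches_exhaustive_oracle(self, rng):
        m, n, k = 200, 20, 10
        X = rng.uniform(size=(m, n))
        mask = rng.random((m, n)) < 0.02
        Xm = X.copy()
        Xm[mask] = np.nan
        out = impute_knn(Xm, k=k)

        obs = ~np.isnan(Xm)
        for j, i in zip(*np.where(mask)):
            # oracle: rescaled Euclidean over shared observed samples
            dists = np.full(m, np.inf)
            for kk in range(m):
                if kk == j or not obs[kk, i]:
                    continue
                shared = obs[j] & obs[kk]
                if not shared.any():
                    continue
                diff = Xm[j, shared] - Xm[kk, shared]
                dists[kk] = n * (diff @ diff) / shared.sum()
            nearest = np.argsort(dists, kind="stable")[:k]
            expected = Xm[nearest, i].mean()
            assert out[j, i] == pytest.approx(expected, abs=1e-10)

    def test_cross_check_against_sklearn_knnimputer(self, rng):
        # independent implementation of the same neighbour rule
        from sklearn.impute import KNNImputer

        m, n, k = 120, 15, 5
        X = rng.uniform(size=(m, n))
        mask = np.zeros((m, n), dtype=bool)
        idx = rng.choice(m * n, 40, replace=False)
        mask.flat[idx] = True
        Xm = X.copy()
        Xm[mask] = np.nan
        mine = impute_knn(Xm, k=k)
        ref = KNNImputer(n_neighbors=k).fit_transform(Xm)
        np.testing.assert_allclose(mine, ref, atol=1e-10)


class TestRankNormal:
    def test_three_values_map_to_blom_quantiles(self):
        sites = pd.DataFrame({"chrom": ["c"] * 3, "pos": [1, 2, 3]})
        out = rank_normal_per_sample(np.array([[0.3], [0.1], [0.9]]), sites)
        a = 3.0 / 8.0
        expected = norm.ppf((np.array([2.0, 1.0, 3.0]) - a) / (3 + 1 - 2 * a))
        np.testing.assert_allclose(out.values[:, 0], expected, atol=1e-12)
        assert out.values[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_spearman_one(self, rng):
        x = rng.uniform(size=500)
        z = rank_normal_vector(x)
        assert spearmanr(x, z).statistic == pytest.approx(1.0)

    def test_formula_oracle_large_sample(self, rng):
        n = 5000
        x = rng.uniform(size=(n, 1))
        sites = pd.DataFrame({"chrom": ["c"] * n, "pos": np.arange(1, n + 1)})
        out = rank_normal_per_sample(x, sites).values[:, 0]
        # direct formula evaluation as the oracle
        ranks = rankdata(x[:, 0])
        oracle = norm.ppf((ranks - 0.5) / n)
        np.testing.assert_allclose(out, oracle, atol=1e-12)
        assert abs(out.mean()) < 1e-3
        assert abs(out.std() / oracle.std() - 1) < 0.01

    def test_per_sample_independence_under_subsetting(self, rng):
        X = rng.uniform(size=(100, 6))
        sites = pd.DataFrame({"chrom": ["c"] * 100, "pos": np.arange(100) + 1})
        full = rank_normal_per_sample(X, sites).values
        sub = rank_normal_per_sample(X[:, [0, 3]], sites).values
        np.testing.assert_array_equal(full[:, [0, 3]], sub)

    def test_requires_complete_data(self):
        sites = pd.DataFrame({"chrom": ["c"] * 3, "pos": [1, 2, 3]})
        X = np.array([[0.1], [np.nan], [0.5]])
        with pytest.raises(ValueError, match="complete"):
            rank_normal_per_sample(X, sites)

    def test_ties_share_mean_rank(self):
        sites = pd.DataFrame({"chrom": ["c"] * 4, "pos": [1, 2, 3, 4]})
        out = rank_normal_per_sample(np.array([[0.5], [0.5], [0.1], [0.9]]),
                                     sites).values[:, 0]
        assert out[0] == out[1]


class TestRankNormalProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                    min_size=2, max_size=200))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_rank_normal_is_monotone_and_bounded(self, values):
        values = np.asarray(values)
        z = rank_normal_vector(values)
        order = np.argsort(values, kind="stable")
        assert (np.diff(z[order]) >= -1e-12).all()
        assert np.isfinite(z).all()
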