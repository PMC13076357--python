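"""Site filtering, kNN imputation and the per-sample rank-normal transform.

Three rules, applied jointly (order-independent), reduce the raw site
universe to the candidate clock sites:

* mean read coverage across all samples (missing cells count as 0) of at
  least ``min_mean_cov`` (default 5x);
* mean methylation ratio over observed samples inside ``meth_bounds``
  (default [0.1, 0.9] inclusive), dropping constitutively hyper- or
  hypomethylated sites;
* missing fraction strictly below ``max_missing_frac`` (default 5%; a site
  missing in exactly 5% of samples is excluded).

Remaining missing ratios are filled by a k-nearest-neighbour rule over
sites, and each sample is then mapped onto standard-normal quantiles by
rank (the ``qqnorm`` convention), independently of every other sample —
which is what lets a single new sample be normalized at prediction time
without any training-state leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .methyl_io import MethylationDataset

__all__ = ["FilterReport", "NormalizedMatrix", "filter_sites", "impute_knn",
           "rank_normal_per_sample", "rank_normal_vector"]


@dataclass
class FilterReport:
    n_input_sites: int
    n_fail_coverage: int
    n_fail_meanmeth: int
    n_fail_missing: int
    n_retained: int
    fail_coverage: np.ndarray | None = None  # boolean masks over input sites
    fail_meanmeth: np.ndarray | None = None
    fail_missing: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input", "coverage", "mean_methylation", "missing",
                         "retained"],
                "n_sites": [self.n_input_sites, self.n_fail_coverage,
                            self.n_fail_meanmeth, self.n_fail_missing,
                            self.n_retained],
            }
        )


@dataclass
class NormalizedMatrix:
    """Sites x samples values after per-sample rank-normalization.

    ``sites`` records the site universe the ranks were computed over; a
    model trained on this matrix must normalize new samples over the same
    universe to reproduce the training-time value distribution.
    """

    values: np.ndarray
    sites: pd.DataFrame
    samples: pd.DataFrame
    mode: str = "rank_normal_per_sample"

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def filter_sites(
    dataset: MethylationDataset,
    min_mean_cov: float = 5.0,
    meth_bounds: tuple[float, float] = (0.1, 0.9),
    max_missing_frac: float = 0.05,
    missing_unit: str = "sample",
    keep_masks: bool = False,
) -> tuple[MethylationDataset, FilterReport]:
    """Apply the three site-level filters; return retained dataset + report.

    ``missing_unit`` selects whether the missing fraction is computed over
    samples (default) or over individuals (an individual counts as missing
    at a site when any of its samples is missing there).
    """
    if missing_unit not in ("sample", "individual"):
        raise ValueError("missing_unit must be 'sample' or 'individual'")
    total = dataset.total
    missing = dataset.missing
    mean_cov = total.mean(axis=1)

    with np.errstate(invalid="ignore"):
        mean_ratio = np.nanmean(
            np.where(missing, np.nan, dataset.ratios), axis=1
        ) if not missing.all() else np.full(dataset.n_sites, np.nan)

    if missing_unit == "sample":
        missing_frac = missing.mean(axis=1)
    else:
        inds = dataset.samples["individual_id"].to_numpy()
        uniq = pd.unique(inds)
        ind_missing = np.zeros((dataset.n_sites, len(uniq)), dtype=bool)
        for j, ind in enumerate(uniq):
            ind_missing[:, j] = missing[:, inds == ind].any(axis=1)
        missing_frac = ind_missing.mean(axis=1)

    lo, hi = meth_bounds
    ok_cov = mean_cov >= min_mean_cov
    # NaN mean ratio (site unobserved everywhere) fails the bounds rule
    ok_meth = (mean_ratio >= lo) & (mean_ratio <= hi)
    ok_miss = missing_frac < max_missing_frac
    retain = ok_cov & ok_meth & ok_miss

    report = FilterReport(
        n_input_sites=dataset.n_sites,
        n_fail_coverage=int((~ok_cov).sum()),
        n_fail_meanmeth=int((~ok_meth).sum()),
        n_fail_missing=int((~ok_miss).sum()),
        n_retained=int(retain.sum()),
        fail_coverage=~ok_cov if keep_masks else None,
        fail_meanmeth=~ok_meth if keep_masks else None,
        fail_missing=~ok_miss if keep_masks else None,
    )
    return dataset.subset_sites(retain), report


def impute_knn(matrix: np.ndarray, k: int = 10, chunk: int = 512) -> np.ndarray:
    """Fill missing ratios by the k-nearest-site rule.

    For a missing cell (site j, sample i) the imputed value is the mean of
    sample i's values at the ``k`` sites closest to j.  Distance between
    two sites is Euclidean over the samples both observe, rescaled by
    ``n_samples / n_shared`` so sites sharing few samples are not
    artificially close; a site with no shared sample is ineligible as a
    donor.  Only sites observed in sample i can donate; when fewer than
    ``k`` are eligible the available donors are averaged.  Sites missing in
    at least half the samples are filled with their own observed mean
    instead.  Observed entries are returned unchanged; imputed values are
    clipped to [0, 1].
    """
    X = np.asarray(matrix, dtype=float)
    m, n = X.shape
    if k >= m:
        raise ValueError(f"k={k} must be smaller than the number of sites ({m})")
    observed = ~np.isnan(X)
    out = X.copy()

    row_missing_frac = 1.0 - observed.mean(axis=1)
    with np.errstate(invalid="ignore"):
        row_means = np.nanmean(np.where(observed, X, np.nan), axis=1)

    heavy = row_missing_frac >= 0.5
    receivers = np.flatnonzero((row_missing_frac > 0) & ~heavy)
    if receivers.size:
        M = observed.astype(float)
        Xz = np.where(observed, X, 0.0)
        Xz2 = Xz * Xz
        MT = M.T
        XzT = Xz.T
        Xz2T = Xz2.T
        for lo_i in range(0, receivers.size, chunk):
            rows = receivers[lo_i:lo_i + chunk]
            sq = Xz2[rows] @ MT + M[rows] @ Xz2T - 2.0 * (Xz[rows] @ XzT)
            shared = M[rows] @ MT
            with np.errstate(divide="ignore", invalid="ignore"):
                d2 = np.where(shared > 0, n * sq / shared, np.inf)
            np.maximum(d2, 0.0, out=d2)  # clamp BLAS round-off
            for r_local, j in enumerate(rows):
                dj = d2[r_local]
                for i in np.flatnonzero(~observed[j]):
                    elig = observed[:, i] & np.isfinite(dj)
                    elig[j] = False
                    idx = np.flatnonzero(elig)
                    if idx.size == 0:
                        out[j, i] = row_means[j]
                        continue
                    kk = min(k, idx.size)
                    nearest = idx[np.argpartition(dj[idx], kk - 1)[:kk]]
                    out[j, i] = X[nearest, i].mean()
    for j in np.flatnonzero(heavy):
        out[j, ~observed[j]] = row_means[j]
    fill = ~observed
    out[fill] = np.clip(out[fill], 0.0, 1.0)
    return out


def _rank_normal_column(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    a = 3.0 / 8.0 if n <= 10 else 0.5
    ranks = rankdata(values, method="average")
    return norm.ppf((ranks - a) / (n + 1.0 - 2.0 * a))


def rank_normal_vector(values: np.ndarray) -> np.ndarray:
    """Rank-normal transform of one sample's ratios over a site universe."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D vector of ratios")
    if values.shape[0] < 2:
        raise ValueError("rank-normalization needs at least 2 sites")
    if np.isnan(values).any():
        raise ValueError("rank-normalization requires complete data")
    return _rank_normal_column(values)


def rank_normal_per_sample(
    matrix: np.ndarray,
    sites: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> NormalizedMatrix:
    """Map each sample's ratios onto standard-normal quantiles by rank.

    Within each sample (column), values are replaced by
    ``Phi^-1((r - a) / (n + 1 - 2a))`` with ``r`` the average rank over the
    site universe, ``n`` the universe size, and ``a = 3/8`` for n <= 10
    else ``1/2`` — the qqnorm plotting-position convention.  Columns are
    transformed independently, so the result for a sample does not depend
    on which other samples are present.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a sites x samples matrix")
    if X.shape[0] != len(sites):
        raise ValueError("matrix rows must align with the site table")
    if X.shape[0] < 2:
        raise ValueError("rank-normalization needs at least 2 sites")
    if np.isnan(X).any():
        raise ValueError("rank-normalization requires complete data (impute first)")
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = _rank_normal_column(X[:, j])
    if samples is None:
        samples = pd.DataFrame(index=range(X.shape[1]))
    return NormalizedMatrix(values=out, sites=sites.reset_index(drop=True),
                            samples=samples.reset_index(drop=True))
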