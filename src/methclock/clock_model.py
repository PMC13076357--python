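"""The epigenetic clock: feature selection, elastic-net fitting with
alpha/lambda tuning, an RBF support-vector comparator, individual-aware
cross-validation, and age prediction.

The clock is a penalized linear model on rank-normalized methylation at a
small set of age-associated CpGs.  Candidate sites are pre-filtered by the
absolute Pearson correlation of their normalized methylation with
chronological age (|r| > 0.5 by default); the surviving features enter an
elastic net whose mixing parameter alpha is grid-searched on
cross-validated R^2 and whose penalty strength lambda is chosen per alpha
by internal n-fold cross-validation on mean squared error.

Because individuals are sampled repeatedly, honest evaluation uses
leave-one-individual-out cross-validation (LOIOCV): every fold holds out
*all* samples of one individual.  Feature selection can run once on the
full data before LOIOCV (``selection_mode="paper"``, the historical
protocol) or be repeated inside each fold (``"nested"``), which quantifies
the optimism introduced by pre-selection.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._enet import cd_path, enet_certified, kkt_residual
from .preprocess import NormalizedMatrix, rank_normal_vector

__all__ = [
    "ClockModel",
    "ENetFit",
    "LOIOCVConfig",
    "stratified_split",
    "select_features",
    "fit_elastic_net",
    "grid_search_alpha",
    "fit_svr_rbf",
    "comparator_table",
    "loiocv",
    "train_clock",
    "predict_age",
]

LAMBDA_MIN_RATIO = 1e-3
N_LAMBDA = 100
MAX_SWEEPS = 100_000
CD_TOL = 1e-7
KKT_TOL = 1e-7
# loose settings for lambda-path exploration inside cross-validation, where
# only the MSE ranking of nearby lambdas matters
PATH_SWEEPS = 200
PATH_TOL = 1e-5
# alpha=0 has an infinite exact lambda_max; the path top is computed at this
# conventional surrogate mixing value instead
ALPHA_FLOOR = 1e-3


# --------------------------------------------------------------------------
# data splitting


def stratified_split(
    samples: pd.DataFrame,
    train_frac: float = 65 / 91,
    n_bins: int = 5,
    seed: int = 0,
    unit: str = "sample",
) -> tuple[list[str], list[str]]:
    """Age-stratified random train/test split.

    Ages are binned by quantiles into ``n_bins`` bins and ``train_frac`` of
    each bin is assigned to training uniformly at random.  With
    ``unit="individual"`` all samples of an individual stay on one side
    (individuals are binned by their mean age).  Returns two lists of
    sample ids.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    if unit not in ("sample", "individual"):
        raise ValueError("unit must be 'sample' or 'individual'")
    rng = np.random.default_rng(seed)
    if unit == "sample":
        units = samples[["sample_id", "age_years"]].rename(
            columns={"sample_id": "uid", "age_years": "age"}
        )
    else:
        units = (
            samples.groupby("individual_id")["age_years"].mean()
            .rename("age").reset_index()
            .rename(columns={"individual_id": "uid"})
        )
    bins = pd.qcut(units["age"], q=min(n_bins, len(units)), duplicates="drop")
    train_units: list = []
    for _, grp in units.groupby(bins, observed=True):
        ids = grp["uid"].to_numpy()
        n_train = int(round(train_frac * len(ids)))
        pick = rng.choice(len(ids), size=n_train, replace=False)
        train_units.extend(ids[pick])
    train_units = set(train_units)
    if unit == "sample":
        train = [s for s in samples["sample_id"] if s in train_units]
        test = [s for s in samples["sample_id"] if s not in train_units]
    else:
        train = [
            s for s, ind in zip(samples["sample_id"], samples["individual_id"])
            if ind in train_units
        ]
        test = [
            s for s, ind in zip(samples["sample_id"], samples["individual_id"])
            if ind not in train_units
        ]
    return train, test


# --------------------------------------------------------------------------
# feature selection


def select_features(
    matrix: NormalizedMatrix | np.ndarray,
    ages: np.ndarray,
    threshold: float = 0.5,
    mode: str = "absolute",
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Correlation filter: sites whose methylation tracks age.

    Computes the per-site Pearson correlation ``r`` between normalized
    methylation and chronological age and keeps sites with ``|r| >
    threshold`` (``mode="absolute"``) or ``r > threshold``
    (``mode="signed"``); the inequality is strict.  Returns a frame with
    columns ``site_index, chrom, pos, r`` ordered by descending |r| then
    site coordinate.  Zero-variance sites are skipped with a warning.
    """
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    if isinstance(matrix, NormalizedMatrix):
        values, sites = matrix.values, matrix.sites
    else:
        values = np.asarray(matrix, dtype=float)
        if sites is None:
            sites = pd.DataFrame(
                {"chrom": "NA", "pos": np.arange(1, values.shape[0] + 1)}
            )
    ages = np.asarray(ages, dtype=float)
    if values.shape[1] != ages.shape[0]:
        raise ValueError("matrix columns must align with ages")
    if ages.shape[0] < 3:
        raise ValueError("need at least 3 samples to correlate with age")

    a = ages - ages.mean()
    sa = np.sqrt((a * a).sum())
    V = values - values.mean(axis=1, keepdims=True)
    sv = np.sqrt((V * V).sum(axis=1))
    zero_var = sv == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance site(s) skipped in "
            "feature selection",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (V @ a) / (sv * sa)
    r[zero_var] = np.nan
    keep = (np.abs(r) > threshold) if mode == "absolute" else (r > threshold)
    keep &= ~np.isnan(r)
    out = pd.DataFrame(
        {
            "site_index": np.flatnonzero(keep),
            "chrom": sites["chrom"].to_numpy()[keep],
            "pos": sites["pos"].to_numpy()[keep],
            "r": r[keep],
        }
    )
    out = out.sort_values(
        by=["r", "chrom", "pos"],
        key=lambda c: -c.abs() if c.name == "r" else c,
        kind="mergesort",
    ).reset_index(drop=True)
    return out


# --------------------------------------------------------------------------
# elastic net


@dataclass
class ENetFit:
    coef: np.ndarray  # on the caller's (unstandardized) feature scale
    intercept: float
    alpha: float
    lam: float
    cv_curve: pd.DataFrame | None = None  # columns: lam, mse
    n_sweeps: int = 0
    kkt: float = float("nan")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.coef


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD so (1/n) x.x = 1
    sd_safe = np.where(sd > 0, sd, 1.0)
    return np.asfortranarray((X - mu) / sd_safe), mu, sd


def _lambda_path(Xs, yc, alpha, n_lambda=N_LAMBDA):
    n = Xs.shape[0]
    a_eff = max(alpha, ALPHA_FLOOR)
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * a_eff)
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, LAMBDA_MIN_RATIO * lam_max, n_lambda)


def _fit_standardized(Xs, yc, alpha, lam, beta0=None,
                      max_sweeps=MAX_SWEEPS, tol=CD_TOL):
    beta, sweeps, _ = enet_certified(
        Xs, yc, alpha, lam, beta0=beta0, tol=tol, kkt_tol=KKT_TOL,
        max_sweeps=max_sweeps,
    )
    return beta, sweeps


def _cv_folds(n: int, n_folds: int, seed: int,
              groups: np.ndarray | None = None) -> np.ndarray:
    """Seeded fold assignment; with groups, whole groups share a fold."""
    rng = np.random.default_rng(seed)
    if groups is None:
        fold = np.repeat(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
        rng.shuffle(fold)
        return fold
    uniq = pd.unique(np.asarray(groups))
    n_folds = min(n_folds, len(uniq))
    order = rng.permutation(len(uniq))
    gfold = {uniq[g]: f % n_folds for f, g in enumerate(order)}
    return np.array([gfold[g] for g in groups])


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float | str = "cv",
    n_folds: int = 10,
    seed: int = 0,
    tol: float = CD_TOL,
    groups: np.ndarray | None = None,
) -> ENetFit:
    """Fit one elastic net; optionally pick lambda by internal CV.

    Features are standardized internally; coefficients come back on the
    caller's scale.  With ``lam="cv"`` a 100-point log-spaced path from
    lambda_max down to 1e-3 * lambda_max is scored by ``n_folds``-fold CV
    on mean squared error and the minimizing lambda is refit on all rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be samples x features aligned with y")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    n = X.shape[0]
    Xs, mu, sd = _standardize(X)
    ybar = y.mean()
    yc = y - ybar

    cv_curve = None
    if isinstance(lam, str):
        if lam != "cv":
            raise ValueError("lam must be a number or 'cv'")
        if n < n_folds:
            n_folds = max(2, n)
        lams = _lambda_path(Xs, yc, alpha)
        fold = _cv_folds(n, n_folds, seed, groups)
        sq_err = np.zeros((len(lams), n))
        for f in np.unique(fold):
            tr, va = fold != f, fold == f
            Xtr, mtr, str_ = _standardize(X[tr])
            ytr = y[tr]
            betas, _ = cd_path(Xtr, ytr - ytr.mean(), alpha, lams,
                               PATH_SWEEPS, PATH_TOL)
            sd_safe = np.where(str_ > 0, str_, 1.0)
            B = betas / sd_safe  # back to caller scale, per lambda
            pred = X[va] @ B.T + (ytr.mean() - mtr @ B.T)
            sq_err[:, va] = ((pred - y[va][:, None]) ** 2).T
        mse = sq_err.mean(axis=1)
        lam = float(lams[int(np.argmin(mse))])
        cv_curve = pd.DataFrame({"lam": lams, "mse": mse})

    beta_s, sweeps = _fit_standardized(Xs, yc, alpha, float(lam), tol=tol)
    kkt = kkt_residual(Xs, yc, beta_s, alpha, float(lam))
    sd_safe = np.where(sd > 0, sd, 1.0)
    coef = np.where(sd > 0, beta_s / sd_safe, 0.0)
    intercept = ybar - float(mu @ coef)
    return ENetFit(coef=coef, intercept=intercept, alpha=alpha, lam=float(lam),
                   cv_curve=cv_curve, n_sweeps=int(sweeps), kkt=kkt)


def grid_search_alpha(
    X: np.ndarray,
    y: np.ndarray,
    alpha_grid: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> tuple[float, float, pd.DataFrame]:
    """Tune the L1/L2 mixing parameter on cross-validated R^2.

    For each alpha on the grid (default 0 to 1 in steps of 0.01), lambda is
    chosen by internal CV on MSE, and the cross-validated R^2 (squared
    Pearson correlation of out-of-fold predictions with age) is recorded.
    Returns ``(best_alpha, best_lambda, table)``; exact R^2 ties go to the
    larger (sparser) alpha.  Folds are shared across alphas and respect
    ``groups`` when given.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    n = X.shape[0]
    if n < n_folds:
        n_folds = max(2, n)
    fold = _cv_folds(n, n_folds, seed, groups)
    uniq_folds = np.unique(fold)

    rows = []
    best = (-np.inf, None, None)
    for alpha in alpha_grid:
        Xs, _, _ = _standardize(X)
        lams = _lambda_path(Xs, y - y.mean(), alpha)
        oof = np.zeros((len(lams), n))
        for f in uniq_folds:
            tr, va = fold != f, fold == f
            Xtr, mtr, sdtr = _standardize(X[tr])
            ytr = y[tr]
            betas, _ = cd_path(Xtr, ytr - ytr.mean(), alpha, lams,
                               PATH_SWEEPS, PATH_TOL)
            sd_safe = np.where(sdtr > 0, sdtr, 1.0)
            B = betas / sd_safe
            oof[:, va] = (X[va] @ B.T + (ytr.mean() - mtr @ B.T)).T
        mse = ((oof - y[None, :]) ** 2).mean(axis=1)
        t_best = int(np.argmin(mse))
        pred = oof[t_best]
        if np.std(pred) == 0 or np.std(y) == 0:
            r2 = -np.inf
        else:
            r2 = float(np.corrcoef(pred, y)[0, 1] ** 2)
        lam_best = float(lams[t_best])
        rows.append({"alpha": float(alpha), "lam": lam_best, "cv_r2": r2})
        if r2 >= best[0]:  # >= : ties break toward larger alpha
            best = (r2, float(alpha), lam_best)
    table = pd.DataFrame(rows)
    return best[1], best[2], table


# --------------------------------------------------------------------------
# SVR comparator


def fit_svr_rbf(X: np.ndarray, y: np.ndarray, C: float = 10.0,
                epsilon: float = 0.1, gamma: str | float = "scale"):
    """Epsilon-SVR with an RBF kernel — the non-linear comparator.

    Thin wrapper over scikit-learn's SMO-based solver; used only to put a
    kernel-regression baseline next to the elastic net in tuning reports.
    """
    from sklearn.svm import SVR

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in X")
    model = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma)
    model.fit(X, y)
    return model


def comparator_table(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.5,
    seed: int = 0,
    n_folds: int = 5,
) -> pd.DataFrame:
    """Grouped-CV comparison of the elastic net and the SVR comparator."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    fold = _cv_folds(len(y), n_folds, seed, groups)
    preds = {"elastic_net": np.zeros_like(y), "svr_rbf": np.zeros_like(y)}
    for f in np.unique(fold):
        tr, va = fold != f, fold == f
        en = fit_elastic_net(X[tr], y[tr], alpha=alpha, lam="cv", seed=seed)
        preds["elastic_net"][va] = en.predict(X[va])
        sv = fit_svr_rbf(X[tr], y[tr])
        preds["svr_rbf"][va] = sv.predict(X[va])
    rows = []
    for name, p in preds.items():
        mae = float(np.mean(np.abs(p - y)))
        r = float(np.corrcoef(p, y)[0, 1]) if np.std(p) > 0 else np.nan
        rows.append({"model": name, "cv_mae": mae, "cv_r": r})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# LOIOCV


@dataclass
class LOIOCVConfig:
    threshold: float = 0.5
    selection_mode: str = "paper"  # or "nested"
    selection_rule: str = "absolute"  # or "signed"
    alpha: float = 0.5
    lam: float | str = "cv"
    n_folds_inner: int = 10
    seed: int = 0


def loiocv(
    matrix: NormalizedMatrix,
    ages: np.ndarray,
    individuals: np.ndarray,
    config: LOIOCVConfig | None = None,
):
    """Leave-one-individual-out cross-validation of the clock pipeline.

    One fold per distinct individual; all of that individual's samples are
    held out, the pipeline is refit on the rest (repeating feature
    selection inside the fold when ``selection_mode="nested"``) and the
    held-out samples are predicted.  Returns ``(predictions, report)``
    where predictions carry one row per sample and the report holds the
    assembled-prediction metrics.
    """
    from .evaluation import compute_metrics

    config = config or LOIOCVConfig()
    ages = np.asarray(ages, dtype=float)
    individuals = np.asarray(individuals)
    uniq = pd.unique(individuals)
    if len(uniq) < 3:
        raise ValueError("LOIOCV needs at least 3 distinct individuals")
    values = matrix.values  # sites x samples

    if config.selection_mode == "paper":
        selected = select_features(
            matrix, ages, threshold=config.threshold, mode=config.selection_rule
        )
        global_idx = selected["site_index"].to_numpy()
        if len(global_idx) == 0:
            raise ValueError("no site passed the correlation threshold")
    elif config.selection_mode != "nested":
        raise ValueError("selection_mode must be 'paper' or 'nested'")

    sample_ids = (
        matrix.samples["sample_id"].to_numpy()
        if "sample_id" in matrix.samples.columns
        else np.array([f"s{i}" for i in range(values.shape[1])])
    )
    dnam = np.full(len(ages), np.nan)
    fold_of = np.empty(len(ages), dtype=object)
    for ind in uniq:
        test = individuals == ind
        train = ~test
        if not train.any():
            raise ValueError(f"individual {ind!r} owns every sample")
        if config.selection_mode == "nested":
            sel = select_features(
                values[:, train], ages[train], threshold=config.threshold,
                mode=config.selection_rule,
                sites=matrix.sites,
            )
            idx = sel["site_index"].to_numpy()
            if len(idx) == 0:
                # no feature survives in this fold: predict the train mean
                dnam[test] = ages[train].mean()
                fold_of[test] = ind
                continue
        else:
            idx = global_idx
        fit = fit_elastic_net(
            values[idx][:, train].T, ages[train], alpha=config.alpha,
            lam=config.lam, n_folds=config.n_folds_inner, seed=config.seed,
        )
        dnam[test] = fit.predict(values[idx][:, test].T)
        fold_of[test] = ind

    preds = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "individual_id": individuals,
            "fold": fold_of,
            "age_years": ages,
            "dnam_age": dnam,
        }
    )
    report = compute_metrics(preds)
    return preds, report


# --------------------------------------------------------------------------
# final model + prediction


@dataclass
class ClockModel:
    """A trained clock: selected CpGs, their coefficients, and the
    normalization universe needed to transform a new sample."""

    candidate_sites: pd.DataFrame  # universe ranks are computed over
    selected: pd.DataFrame  # site_index, chrom, pos, r
    coefficients: np.ndarray  # one per selected site
    intercept: float
    alpha: float
    lam: float
    selection_threshold: float = 0.5
    selection_mode: str = "paper"
    site_means: np.ndarray | None = None  # training mean ratio per candidate

    def __post_init__(self):
        if len(self.selected) != len(self.coefficients):
            raise ValueError("one coefficient per selected site required")
        if not self.selected["site_index"].isin(
            range(len(self.candidate_sites))
        ).all():
            raise ValueError("selected sites must lie in the candidate universe")

    @property
    def universe_hash(self) -> str:
        h = hashlib.sha256()
        for chrom, pos in self.candidate_sites[["chrom", "pos"]].itertuples(
            index=False
        ):
            h.update(f"{chrom}:{pos};".encode())
        return h.hexdigest()

    def to_json(self, path=None) -> str:
        doc = {
            "format": "methclock-model-v1",
            "candidate_sites": {
                "chrom": self.candidate_sites["chrom"].tolist(),
                "pos": self.candidate_sites["pos"].astype(int).tolist(),
            },
            "selected": {
                "site_index": self.selected["site_index"].astype(int).tolist(),
                "chrom": self.selected["chrom"].tolist(),
                "pos": self.selected["pos"].astype(int).tolist(),
                "r": self.selected["r"].tolist(),
            },
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "alpha": self.alpha,
            "lam": self.lam,
            "selection_threshold": self.selection_threshold,
            "selection_mode": self.selection_mode,
            "site_means": None if self.site_means is None
            else self.site_means.tolist(),
            "universe_hash": self.universe_hash,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ClockModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            candidate_sites=pd.DataFrame(doc["candidate_sites"]),
            selected=pd.DataFrame(doc["selected"]),
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            intercept=float(doc["intercept"]),
            alpha=float(doc["alpha"]),
            lam=float(doc["lam"]),
            selection_threshold=float(doc["selection_threshold"]),
            selection_mode=doc["selection_mode"],
            site_means=None if doc["site_means"] is None
            else np.asarray(doc["site_means"], dtype=float),
        )


def train_clock(
    matrix: NormalizedMatrix,
    ages: np.ndarray,
    threshold: float = 0.5,
    selection_rule: str = "absolute",
    alpha: float | None = None,
    alpha_grid: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    seed: int = 0,
    ratios: np.ndarray | None = None,
) -> tuple[ClockModel, pd.DataFrame | None]:
    """Select features and fit the final clock on all provided samples.

    When ``alpha`` is None it is tuned by :func:`grid_search_alpha` (the
    tuning table is returned alongside the model).  ``ratios`` — the raw
    ratio matrix over the candidate universe — supplies the per-site
    training means stored for prediction-time gap filling.
    """
    ages = np.asarray(ages, dtype=float)
    selected = select_features(matrix, ages, threshold=threshold,
                               mode=selection_rule)
    if len(selected) == 0:
        raise ValueError("no site passed the correlation threshold")
    idx = selected["site_index"].to_numpy()
    X = matrix.values[idx].T
    table = None
    if alpha is None:
        alpha, lam, table = grid_search_alpha(
            X, ages, alpha_grid=alpha_grid, groups=groups, seed=seed
        )
        fit = fit_elastic_net(X, ages, alpha=alpha, lam=lam, seed=seed)
    else:
        fit = fit_elastic_net(X, ages, alpha=alpha, lam="cv", seed=seed)
    site_means = None
    if ratios is not None:
        with np.errstate(invalid="ignore"):
            site_means = np.nanmean(ratios, axis=1)
    model = ClockModel(
        candidate_sites=matrix.sites.reset_index(drop=True),
        selected=selected,
        coefficients=fit.coef,
        intercept=fit.intercept,
        alpha=fit.alpha,
        lam=fit.lam,
        selection_threshold=threshold,
        site_means=site_means,
    )
    return model, table


def predict_age(model: ClockModel, ratios: np.ndarray) -> float:
    """Predict DNAm age (years) for one sample.

    ``ratios`` is the sample's methylation-ratio vector aligned to the
    model's candidate universe; NaN marks absent sites.  Up to 5% of the
    universe may be absent (filled with stored training means); the sample
    is then rank-normalized over the full universe and the affine clock
    applied.  Predictions are not clamped: negative ages are reported
    as-is.
    """
    ratios = np.asarray(ratios, dtype=float).copy()
    n = len(model.candidate_sites)
    if ratios.shape != (n,):
        raise ValueError(
            f"expected a ratio vector over the {n}-site candidate universe"
        )
    absent = np.isnan(ratios)
    if absent.mean() > 0.05:
        raise ValueError(
            f"{absent.sum()} of {n} candidate sites absent (> 5%); the sample "
            "does not cover the clock's universe — re-sequence or relax the "
            "universe"
        )
    if absent.any():
        if model.site_means is None:
            raise ValueError(
                "sample has absent sites but the model stores no training "
                "site means"
            )
        ratios[absent] = model.site_means[absent]
    z = rank_normal_vector(ratios)
    x = z[model.selected["site_index"].to_numpy()]
    return float(model.intercept + x @ model.coefficients)
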