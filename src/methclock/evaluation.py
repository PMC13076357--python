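"""Scoring, age-acceleration residuals, age-class statistics, PCA and
sex-effect models for clock predictions.

Conventions: R^2 is reported as the squared Pearson correlation of
predicted versus chronological age (the pairing used throughout the
clock literature when quoted next to r); the residual-based
1 - SSE/SST variant is computed and labelled separately.  The relative
error of the clock is 100 * MAE / maximum recorded lifespan, defaulting
to the 79.6-year record for Asian elephants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MAX_LIFESPAN_YEARS",
    "AGE_CLASSES",
    "EvaluationReport",
    "compute_metrics",
    "delta_age_residuals",
    "assign_age_class",
    "compare_age_classes",
    "pca_project",
    "sitewise_sex_model",
]

#: maximum recorded lifespan of the Asian elephant, in years
MAX_LIFESPAN_YEARS = 79.6

#: life-history stages: label -> [lo, hi) in years; seniors are open-ended.
AGE_CLASSES = {
    "calf": (0.0, 1.0),
    "juvenile": (1.0, 5.0),
    "subadult": (5.0, 20.0),
    "adult": (20.0, 50.0),
    "senior": (50.0, np.inf),
}

_CLASS_ORDER = list(AGE_CLASSES)


@dataclass
class EvaluationReport:
    n_samples: int
    mae: float
    pearson_r: float
    r2: float  # squared Pearson correlation
    r2_residual: float  # 1 - SSE/SST
    relative_error_pct: float
    max_lifespan_used: float


def compute_metrics(
    predictions: pd.DataFrame, max_lifespan: float = MAX_LIFESPAN_YEARS
) -> EvaluationReport:
    """Score assembled predictions against chronological age.

    Expects columns ``age_years`` and ``dnam_age``.  MAE is in years;
    relative error is 100 * MAE / max_lifespan (percent).
    """
    y = predictions["age_years"].to_numpy(float)
    p = predictions["dnam_age"].to_numpy(float)
    if len(y) < 2:
        raise ValueError("need at least 2 predictions")
    if np.std(y) == 0 or np.std(p) == 0:
        raise ValueError("zero variance: correlation undefined")
    mae = float(np.mean(np.abs(p - y)))
    r = float(np.corrcoef(p, y)[0, 1])
    sse = float(((y - p) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    return EvaluationReport(
        n_samples=len(y),
        mae=mae,
        pearson_r=r,
        r2=r * r,
        r2_residual=1.0 - sse / sst,
        relative_error_pct=100.0 * mae / max_lifespan,
        max_lifespan_used=max_lifespan,
    )


def delta_age_residuals(predictions: pd.DataFrame) -> pd.Series:
    """Age-acceleration residuals: DNAm age regressed on chronological age.

    Ordinary least squares of ``dnam_age`` on ``age_years``; the residuals
    (mean zero by construction) are the per-sample delta-age values —
    positive means epigenetically older than expected for the chronological
    age.
    """
    y = predictions["dnam_age"].to_numpy(float)
    x = predictions["age_years"].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0:
        raise ValueError("constant chronological age: slope undefined")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=predictions.index, name="delta_age")


def assign_age_class(age_years: float) -> str:
    """Map an age in years to its life-history stage.

    Boundaries are half-open on the left value: [0,1) calf, [1,5)
    juvenile, [5,20) subadult, [20,50) adult, [50, inf) senior.
    """
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    for label, (lo, hi) in AGE_CLASSES.items():
        if lo <= age_years < hi:
            return label
    raise AssertionError("age classes must partition [0, inf)")


def _compact_letters(labels: list[str], sig: dict[tuple[str, str], bool]) -> dict:
    """Compact letter display: groups not significantly different share a
    letter (insert-and-absorb on the non-significance graph)."""
    letter_sets: list[set[str]] = [set(labels)]
    for (a, b), is_sig in sig.items():
        if not is_sig:
            continue
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        letter_sets = [
            s for s in new_sets
            if s and not any(s < t for t in new_sets)
        ]
        # deduplicate
        uniq = []
        for s in letter_sets:
            if s not in uniq:
                uniq.append(s)
        letter_sets = uniq
    letters = {}
    for i, s in enumerate(letter_sets):
        ch = chr(ord("a") + i)
        for lab in s:
            letters.setdefault(lab, "")
            letters[lab] += ch
    return {lab: "".join(sorted(v)) for lab, v in letters.items()}


def compare_age_classes(
    predictions: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """One-way ANOVA of DNAm age across life-history stages plus post hoc
    pairwise Welch t-tests with Benjamini-Hochberg adjustment.

    Returns ``{"anova_F", "anova_p", "pairwise": DataFrame,
    "letters": {class: letters}, "group_means": Series}``.  Classes with
    fewer than 2 samples are dropped with a warning.
    """
    df = predictions.copy()
    if "age_class" not in df.columns:
        df["age_class"] = [assign_age_class(a) for a in df["age_years"]]
    groups = {}
    for label, grp in df.groupby("age_class"):
        if len(grp) < 2:
            warnings.warn(f"age class {label!r} has < 2 samples; dropped",
                          stacklevel=2)
            continue
        groups[label] = grp["dnam_age"].to_numpy(float)
    if len(groups) < 2:
        raise ValueError("need at least 2 classes with >= 2 samples")
    order = [c for c in _CLASS_ORDER if c in groups]
    F, p = stats.f_oneway(*[groups[c] for c in order])

    rows = []
    for a, b in combinations(order, 2):
        t, pv = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append({"class_a": a, "class_b": b, "t": float(t),
                     "p": float(pv)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    sig = {
        (r.class_a, r.class_b): r.p_adj < alpha
        for r in pairwise.itertuples()
    }
    letters = _compact_letters(order, sig)
    means = pd.Series({c: groups[c].mean() for c in order}, name="mean_dnam_age")
    return {
        "anova_F": float(F),
        "anova_p": float(p),
        "pairwise": pairwise,
        "letters": letters,
        "group_means": means,
    }


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration on 1/trigamma."""
    from scipy.special import polygamma

    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += step
        if abs(step) < 1e-8 * y:
            break
    return y


def _moderate_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-site residual variances.

    Fits a scaled inverse-chi-square prior to the observed variances by
    the method of moments on log s2 and returns the posterior variances
    together with the augmented degrees of freedom (prior + residual) —
    the moderated-t construction used throughout site-wise differential
    analyses.  With many sites and few samples this removes the spuriously
    tiny variances that otherwise dominate the far tail of the t
    statistics.
    """
    from scipy.special import digamma, polygamma

    z = np.log(s2)
    e = z - float(digamma(df / 2.0)) + np.log(df / 2.0)
    excess = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if excess <= 0:
        # no evidence of variance heterogeneity: pool completely
        return np.full_like(s2, np.exp(e.mean())), float("inf")
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(e.mean() + float(digamma(d0 / 2.0)) - np.log(d0 / 2.0))
    return (d0 * s0_sq + df * s2) / (d0 + df), d0 + df


def pca_project(matrix: np.ndarray, scale: bool = True):
    """PCA of samples over (clock) sites with unit-scaled columns.

    ``matrix`` is sites x samples; rows are treated as variables and
    samples as observations.  Zero-variance sites are dropped with a
    warning.  Returns ``(scores, loadings, variance_fractions)`` with the
    sign convention that each component's largest-magnitude loading is
    positive.
    """
    X = np.asarray(matrix, dtype=float).T  # samples x sites
    n, m = X.shape
    if n < 3 or m < 2:
        raise ValueError("need >= 3 samples and >= 2 sites")
    sd = X.std(axis=0)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-variance site(s) dropped "
                      "from PCA", stacklevel=2)
        X = X[:, sd > 0]
        sd = sd[sd > 0]
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * S
    var_frac = S**2 / np.sum(S**2)
    return scores, Vt.T, var_frac


def sitewise_sex_model(
    matrix: np.ndarray,
    predictions: pd.DataFrame,
    fdr: float = 0.05,
    transform: str = "rank_normal",
) -> dict:
    """Per-site linear models testing sex effects at clock CpGs.

    For every site, methylation is modelled as
    ``meth ~ dnam_age + sex + dnam_age:sex``; the reported per-site p-value
    is the smaller of the sex main-effect and interaction p-values, with a
    flag naming the winning term.  Because the minimum over two tests is
    anti-conservative, the per-site p is Bonferroni-doubled before BH
    adjustment across sites; q < ``fdr`` flags a site.  A companion
    Gaussian model of the age-acceleration residuals (``delta_age ~ sex``
    and ``delta_age ~ sex + age``) is reported alongside.

    By default each site's values are mapped onto normal quantiles by rank
    before fitting (``transform="rank_normal"``): methylation ratios are
    bounded and heteroskedastic, and with a small minority sex the far
    tail of the t reference is otherwise anti-conservative.  Pass
    ``transform="none"`` to model raw values.  Per-site variances are
    moderated by empirical-Bayes shrinkage (the moderated-t construction),
    which removes the spuriously small variances that dominate the far
    tail when many sites are tested on few samples.

    ``matrix`` is sites x samples over the clock CpGs, aligned with
    ``predictions`` (columns ``dnam_age``, ``age_years``, ``sex`` coded
    F/M; samples with unknown sex are excluded).  Raises when either sex
    has fewer than 3 samples.
    """
    if transform not in ("rank_normal", "none"):
        raise ValueError("transform must be 'rank_normal' or 'none'")
    sex = predictions["sex"].to_numpy()
    known = np.isin(sex, ("F", "M"))
    matrix = np.asarray(matrix, float)[:, known]
    preds = predictions.loc[known].reset_index(drop=True)
    sex = sex[known]
    n_f, n_m = int((sex == "F").sum()), int((sex == "M").sum())
    if min(n_f, n_m) < 3:
        raise ValueError(
            f"sex model needs >= 3 samples of each sex (got F={n_f}, M={n_m})"
        )
    age = preds["dnam_age"].to_numpy(float)
    is_m = (sex == "M").astype(float)
    X = np.column_stack([np.ones_like(age), age, is_m, age * is_m])
    n, k = X.shape
    dof = n - k
    if dof < 1:
        raise ValueError("not enough samples for the 4-parameter sex model")

    # multi-response OLS: one design, all sites at once
    Y = matrix.T  # samples x sites
    if transform == "rank_normal":
        ranks = stats.rankdata(Y, axis=0)
        Y = stats.norm.ppf((ranks - 0.5) / Y.shape[0])
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # k x sites
    resid = Y - X @ B
    s2 = (resid**2).sum(axis=0) / dof
    s2_mod, dof_mod = _moderate_variances(s2, dof)
    se = np.sqrt(np.outer(np.diag(XtX_inv), s2_mod))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = B / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof_mod)

    p_sex, p_int = pvals[2], pvals[3]
    p_min = np.minimum(p_sex, p_int)
    term = np.where(p_sex <= p_int, "sex", "age:sex")
    # taking the smaller of two per-site tests is itself a multiple test:
    # Bonferroni within site, then BH across sites, keeps the FDR at its
    # nominal level
    qvals = multipletests(np.minimum(2.0 * p_min, 1.0), method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "p_sex": p_sex,
            "p_interaction": p_int,
            "p": p_min,
            "term": term,
            "q": qvals,
            "flagged": qvals < fdr,
        }
    )

    # companion delta-age models
    import statsmodels.api as sm

    delta = delta_age_residuals(preds).to_numpy()
    chron = preds["age_years"].to_numpy(float)
    m1 = sm.GLM(delta, sm.add_constant(is_m),
                family=sm.families.Gaussian()).fit()
    m2 = sm.GLM(delta, sm.add_constant(np.column_stack([is_m, chron])),
                family=sm.families.Gaussian()).fit()
    delta_model = {
        "p_sex": float(m1.pvalues[1]),
        "p_sex_age_adjusted": float(m2.pvalues[1]),
        "coef_sex": float(m1.params[1]),
    }
    return {"sites": table, "n_flagged": int(table["flagged"].sum()),
            "delta_age_model": delta_model}
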