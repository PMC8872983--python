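"""Psychometric validation of test scores.

Covers the descriptive half of the pipeline: covariate adjustment by OLS
residualization, composite construction, internal-consistency and retest
reliability, dimensionality (PCA with parallel analysis and a one-factor
confirmatory model), sex differences, convergent-validity profile
comparison, and screening for careless responders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import f as f_dist
from scipy.stats import norm, pearsonr

from ._types import ResponseMatrix

__all__ = [
    "adjust_and_standardize",
    "composite",
    "cronbach_alpha",
    "reliability",
    "retest_reliability",
    "pca_with_parallel",
    "one_factor_cfa",
    "sex_anova",
    "convergent_profile",
    "ClickerConfig",
    "detect_clickers",
]


def _design_from_covariates(cov: pd.DataFrame) -> np.ndarray:
    """Numeric design matrix: sex/age as-is, screen size as two dummies."""
    cols = [np.ones(len(cov))]
    for name in cov.columns:
        col = cov[name]
        if name == "screen_size" or col.dtype == object or isinstance(
                col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True)
            for dcol in dummies.columns:
                cols.append(dummies[dcol].to_numpy(float))
        else:
            cols.append(col.to_numpy(float))
    return np.column_stack(cols)


def adjust_and_standardize(
    scores: pd.DataFrame | pd.Series,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Z-scored OLS residuals of each score on the covariates.

    Categorical covariates (screen size) enter as dummy variables.  The
    residuals are exactly orthogonal to every covariate column and are
    returned with mean 0, SD 1.  A score that is an exact linear function
    of the covariates (zero residual variance) is an error.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    if len(scores) != len(covariates):
        raise ValueError("scores and covariates must have equal length")
    x = _design_from_covariates(covariates)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("singular covariate design (collinear columns)")
    out = {}
    for name in scores.columns:
        y = scores[name].to_numpy(float)
        if np.std(y) == 0:
            raise ValueError(f"score {name!r} has zero variance")
        coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        sd = resid.std()
        if sd < 1e-12:
            raise ValueError(
                f"score {name!r} is an exact function of the covariates")
        out[name] = (resid - resid.mean()) / sd
    return pd.DataFrame(out, index=scores.index)


def composite(
    data: pd.DataFrame,
    scheme: str = "sum_items",
) -> pd.DataFrame:
    """Composite scores: item sums or the mean of standardized test scores.

    Subjects missing any component get a missing composite (all components
    are required).  Returns the composite plus the per-subject count of
    contributing components.
    """
    if data.shape[1] < 1:
        raise ValueError("at least one component required")
    n_present = data.notna().sum(axis=1)
    complete = n_present == data.shape[1]
    if scheme == "sum_items":
        vals = data.sum(axis=1)
    elif scheme == "mean_of_standardized_tests":
        z = (data - data.mean()) / data.std(ddof=1)
        vals = z.mean(axis=1)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    vals = vals.where(complete)
    return pd.DataFrame({"composite": vals, "n_components": n_present})


# ---------------------------------------------------------------------------
# reliability


def cronbach_alpha(items: pd.DataFrame) -> float:
    """alpha = k/(k-1) (1 - sum item variances / total-score variance)."""
    k = items.shape[1]
    if k < 2:
        raise ValueError("alpha needs at least two items")
    item_vars = items.var(axis=0, ddof=1).to_numpy()
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def retest_reliability(session1: pd.Series, session2: pd.Series) -> dict:
    """Pearson retest correlation with a Fisher-z 95% CI on matched subjects."""
    joined = pd.concat([session1, session2], axis=1, join="inner").dropna()
    if len(joined) < 4:
        raise ValueError("need at least 4 matched subjects")
    r, p = pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
    z = np.arctanh(r)
    half = norm.ppf(0.975) / np.sqrt(len(joined) - 3)
    return {"r": float(r), "p": float(p), "n": len(joined),
            "ci_low": float(np.tanh(z - half)),
            "ci_high": float(np.tanh(z + half))}


def reliability(items: pd.DataFrame,
                sessions: tuple[pd.Series, pd.Series] | None = None) -> dict:
    """Internal consistency (alpha, one-factor omega) plus optional retest."""
    out = {"alpha": cronbach_alpha(items)}
    cfa = one_factor_cfa(items)
    lam = cfa["loadings"]
    total_var = np.sum(lam) ** 2 + np.sum(cfa["uniquenesses"])
    out["omega_h"] = float(np.sum(lam) ** 2 / total_var)
    if sessions is not None:
        out["retest"] = retest_reliability(*sessions)
    return out


# ---------------------------------------------------------------------------
# dimensionality


def pca_with_parallel(
    data: pd.DataFrame,
    n_reps: int = 500,
    quantile: float = 0.95,
    seed: int = 0,
) -> dict:
    """PCA of the correlation matrix with permutation parallel analysis.

    The null eigenvalues come from independently permuting each column,
    which preserves marginals but destroys correlation.  A component is
    retained when its observed eigenvalue exceeds the null quantile;
    adjusted eigenvalues are observed minus null mean plus 1.
    """
    x = data.to_numpy(float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least two variables")
    if n <= k:
        raise ValueError("need more observations than variables")
    corr = np.corrcoef(x, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    rng = np.random.default_rng(seed)
    null = np.empty((n_reps, k))
    for rep in range(n_reps):
        perm = np.column_stack([rng.permutation(x[:, j]) for j in range(k)])
        null[rep] = np.sort(np.linalg.eigvalsh(np.corrcoef(perm, rowvar=False)))[::-1]
    null_q = np.quantile(null, quantile, axis=0)
    retained = int(np.argmin(eigvals > null_q)) if not np.all(eigvals > null_q) \
        else k
    loadings = eigvecs * np.sqrt(np.maximum(eigvals, 0.0))
    return {
        "eigenvalues": eigvals,
        "proportions": eigvals / k,
        "loadings": pd.DataFrame(loadings, index=data.columns,
                                 columns=[f"PC{i + 1}" for i in range(k)]),
        "null_quantiles": null_q,
        "adjusted_eigenvalues": eigvals - null.mean(axis=0) + 1.0,
        "n_retained": retained,
        "scores": pd.DataFrame(
            ((x - x.mean(0)) / x.std(0)) @ eigvecs,
            index=data.index, columns=[f"PC{i + 1}" for i in range(k)]),
    }


def one_factor_cfa(data: pd.DataFrame) -> dict:
    """Single-factor ML confirmatory model with fit indices.

    Minimizes the normal-theory discrepancy F = log|Sigma| + tr(S Sigma^-1)
    - log|S| - p with Sigma = lambda lambda' + diag(psi).  CFI and TLI are
    computed against the independence baseline, SRMR over the correlation
    residuals.  A Heywood case (psi <= 0) is reported in the result, not
    silently truncated.  Factor scores use the regression method.
    """
    x = data.to_numpy(float)
    n, p = x.shape
    if p < 3:
        raise ValueError("one-factor model needs at least 3 indicators")
    s = np.cov(x, rowvar=False, ddof=1)
    if np.linalg.eigvalsh(s).min() <= 0:
        raise ValueError("sample covariance is not positive definite")
    sign, logdet_s = np.linalg.slogdet(s)

    sd = np.sqrt(np.diag(s))
    corr = s / np.outer(sd, sd)
    ev, evec = np.linalg.eigh(corr)
    lam0 = evec[:, -1] * np.sqrt(ev[-1]) * sd
    psi0 = np.maximum(np.diag(s) - lam0 ** 2, 0.05 * np.diag(s))

    def f_ml(theta):
        lam = theta[:p]
        psi = theta[p:]
        if np.any(psi <= 0):
            return np.inf
        sigma = np.outer(lam, lam) + np.diag(psi)
        sgn, logdet = np.linalg.slogdet(sigma)
        if sgn <= 0:
            return np.inf
        return logdet + float(np.trace(np.linalg.solve(sigma, s))) - logdet_s - p

    res = minimize(f_ml, np.concatenate([lam0, psi0]), method="L-BFGS-B",
                   bounds=[(None, None)] * p + [(1e-8, None)] * p,
                   options={"maxiter": 2000})
    lam = res.x[:p]
    psi = res.x[p:]
    if lam.sum() < 0:
        lam = -lam  # sign convention: positive loading sum
    heywood = bool(np.any(psi <= 1e-6))

    fmin = float(res.fun)
    chi2_model = max((n - 1) * fmin, 0.0)
    df_model = p * (p + 1) // 2 - 2 * p
    # independence baseline: diagonal Sigma
    f_base = float(-logdet_s + np.sum(np.log(np.diag(s))))
    chi2_base = max((n - 1) * f_base, 0.0)
    df_base = p * (p - 1) // 2
    num = max(chi2_model - df_model, 0.0)
    den = max(chi2_base - df_base, num, 1e-12)
    cfi = 1.0 - num / den
    tli = ((chi2_base / df_base - chi2_model / max(df_model, 1))
           / max(chi2_base / df_base - 1.0, 1e-12))
    sigma = np.outer(lam, lam) + np.diag(psi)
    sd_m = np.sqrt(np.diag(sigma))
    resid = s / np.outer(sd, sd) - sigma / np.outer(sd_m, sd_m)
    srmr = float(np.sqrt(np.sum(np.tril(resid) ** 2) / (p * (p + 1) / 2)))

    # regression-method factor scores (factor variance fixed at 1)
    weights = np.linalg.solve(sigma, lam)
    centered = x - x.mean(axis=0)
    scores = centered @ weights

    return {
        "loadings": lam,
        "uniquenesses": psi,
        "heywood": heywood,
        "converged": bool(res.success),
        "f_min": fmin,
        "chi2": chi2_model,
        "df": df_model,
        "cfi": float(min(cfi, 1.0)),
        "tli": float(min(tli, 1.0)),
        "srmr": srmr,
        "factor_scores": pd.Series(scores, index=data.index),
    }


# ---------------------------------------------------------------------------
# group differences and validity


def sex_anova(scores: pd.Series | np.ndarray, sex: pd.Series | np.ndarray) -> dict:
    """One-way ANOVA of a score on sex; eta^2 = SS_between / SS_total."""
    y = np.asarray(scores, float)
    g = np.asarray(sex)
    groups = [y[g == lev] for lev in pd.unique(g)]
    if len(groups) != 2:
        raise ValueError("exactly two sex groups required")
    if min(len(grp) for grp in groups) < 2:
        raise ValueError("each group needs n >= 2")
    grand = y.mean()
    ss_between = sum(len(grp) * (grp.mean() - grand) ** 2 for grp in groups)
    ss_within = sum(((grp - grp.mean()) ** 2).sum() for grp in groups)
    ss_total = ss_between + ss_within
    df_b, df_w = 1, len(y) - 2
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    return {
        "F": float(f_stat),
        "p": float(f_dist.sf(f_stat, df_b, df_w)),
        "eta2": float(ss_between / ss_total) if ss_total > 0 else 0.0,
        "df": (df_b, df_w),
    }


def convergent_profile(profile_new, profile_reference) -> float:
    """Similarity of two correlation profiles over the same criteria."""
    a = np.asarray(profile_new, float)
    b = np.asarray(profile_reference, float)
    if a.shape != b.shape:
        raise ValueError("profiles must cover the same criteria")
    if len(a) < 3:
        raise ValueError("need at least 3 criteria")
    return float(pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# careless-responder screening


@dataclass
class ClickerConfig:
    """Thresholds of the careless-responder rules.

    A subject is flagged when any of: at least ``qc_fail_min`` QC items
    answered incorrectly; mean response time below ``rapid_fraction`` of
    the cohort median; a run of at least ``uniform_run`` identical chosen
    options; or a raw score below ``low_score_fraction`` of the cohort
    median score *together with* any other indicator.  The low-score cut
    is anchored to the median rather than a low quantile so that a
    cluster of careless respondents cannot drag the threshold below
    itself.
    """

    qc_fail_min: int = 2
    rapid_fraction: float = 0.2
    uniform_run: int = 15
    low_score_fraction: float = 0.5
    require_qc_items: bool = True


def _longest_run(row: np.ndarray) -> int:
    best = run = 1
    for i in range(1, len(row)):
        run = run + 1 if row[i] == row[i - 1] else 1
        best = max(best, run)
    return best


def detect_clickers(
    responses: ResponseMatrix,
    config: ClickerConfig | None = None,
    choices: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flag careless respondents with per-rule reason codes.

    Returns a frame indexed by subject with boolean columns ``qc_fail``,
    ``rapid``, ``uniform``, ``low_score``, and the overall ``is_clicker``
    flag.  The low-score rule only counts when another indicator also
    fires, so genuinely low-ability attentive subjects are not excluded.
    """
    cfg = config or ClickerConfig()
    qc_items = responses.qc_items
    if cfg.require_qc_items and not qc_items:
        raise ValueError("QC-failure rule enabled but the bank has no QC items")
    acc = responses.accuracy
    subjects = acc.index

    if qc_items:
        qc_fail = (1 - acc[qc_items]).sum(axis=1) >= cfg.qc_fail_min
    else:
        qc_fail = pd.Series(False, index=subjects)

    mean_rt = responses.rt[responses.scored_items].mean(axis=1)
    rapid = mean_rt < cfg.rapid_fraction * mean_rt.median()

    raw = responses.accuracy[responses.scored_items].sum(axis=1)
    low_score = raw <= cfg.low_score_fraction * raw.median()

    uniform = pd.Series(False, index=subjects)
    chosen = choices if choices is not None else getattr(responses, "choices", None)
    if chosen is not None:
        runs = np.array([_longest_run(row) for row in
                         chosen[responses.scored_items].to_numpy()])
        uniform = pd.Series(runs >= cfg.uniform_run, index=subjects)

    # the low-score rule needs corroboration: any soft indicator (a single
    # QC miss counts here, below the hard qc_fail threshold) must co-occur
    if qc_items:
        soft_qc = (1 - acc[qc_items]).sum(axis=1) >= 1
    else:
        soft_qc = pd.Series(False, index=subjects)
    corroborated = low_score & (soft_qc | rapid | uniform)
    flagged = qc_fail | rapid | uniform | corroborated
    out = pd.DataFrame({
        "qc_fail": qc_fail,
        "rapid": rapid,
        "uniform": uniform,
        "low_score": corroborated,
        "is_clicker": flagged,
    })
    out.index.name = "subject_id"
    return out
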