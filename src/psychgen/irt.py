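"""Item response theory: MML calibration, information curves, EAP scoring,
and information-based test shortening.

The calibration is marginal maximum likelihood via the EM algorithm with
Gauss-Hermite quadrature over a standard-normal ability prior.  Items are
parameterized internally as slope/intercept (a, d) with P = expit(a*theta + d),
so that items with vanishing discrimination (whose difficulty b = -d/a is
unidentified) remain numerically well behaved; difficulty is reported as
b = -d/a.  The 3PL adds a guessing asymptote c with a Beta(2, 10)
stabilizing prior — without one, marginal ML for the lower asymptote is
ill-posed on realistic sample sizes.

Test shortening proceeds in three stages over the fitted information
curves: (1) drop items whose information curve is essentially flat,
(2) drop items that never reach an information threshold or whose
difficulty falls outside the target ability range, (3) within selected
domains, drop flat-ICC and redundant items (near-identical characteristic
curves) and then the least informative items until a per-domain quota is
reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "IrtFit",
    "ReductionConfig",
    "fit_irt",
    "icc",
    "item_information",
    "eap_scores",
    "reduce_items",
]

DEFAULT_GRID = np.linspace(-4.0, 4.0, 81)

# Stability bounds on the slope/intercept parameterization.  Unbounded MML
# slopes can diverge on small samples (quasi-Heywood items); a slope of 6
# is already a near-Guttman item on the N(0, 1) ability scale.
A_MAX = 6.0
D_MAX = 40.0


def _gh_nodes(n_quadrature: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights rescaled to integrate against N(0, 1)."""
    x, w = np.polynomial.hermite_e.hermegauss(n_quadrature)
    return x, w / w.sum()


@dataclass
class IrtFit:
    """Calibrated item parameters plus fit and convergence bookkeeping."""

    model: str
    params: pd.DataFrame  # item_id index; a, b, c, se_a, se_b
    loglik: float
    n_subjects: int
    n_items: int
    n_quadrature: int
    converged: bool
    n_iter: int
    final_change: float
    loglik_trace: np.ndarray
    dropped_items: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        per_item = {"1PL": 1, "2PL": 2, "3PL": 3}[self.model]
        k = per_item * self.n_items
        if self.model == "1PL":
            k += 1  # the common slope
        return k

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_subjects)

    @property
    def adjusted_bic(self) -> float:
        n_star = (self.n_subjects + 2.0) / 24.0
        return -2.0 * self.loglik + self.n_params * np.log(n_star)


def _prep_responses(responses) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(responses, pd.DataFrame):
        items = [str(col) for col in responses.columns]
        x = responses.to_numpy(float)
    else:
        x = np.asarray(responses, float)
        items = [f"item{j + 1}" for j in range(x.shape[1])]
    obs = ~np.isnan(x)
    vals = np.unique(x[obs])
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("responses must be binary (0/1) or missing")
    return x, obs, items


def _estep(x, obs, nodes, weights, a, d, c):
    """Posterior weights over quadrature nodes and expected item counts."""
    lin = np.outer(nodes, a) + d  # Q x J
    p = c + (1.0 - c) * expit(lin)
    p = np.clip(p, 1e-10, 1.0 - 1e-10)
    logp, log1p = np.log(p), np.log1p(-p)
    x0 = np.where(obs, x, 0.0)
    # log L_iq = sum_j obs_ij * (x_ij log p_qj + (1 - x_ij) log(1 - p_qj))
    ll = x0 @ logp.T + (obs & (x0 == 0.0)) @ log1p.T  # N x Q
    ll += np.log(weights)
    mx = ll.max(axis=1, keepdims=True)
    post = np.exp(ll - mx)
    norm = post.sum(axis=1, keepdims=True)
    post /= norm
    loglik = float(np.sum(np.log(norm.ravel()) + mx.ravel()))
    nq = post.T @ obs        # Q x J expected counts
    rq = post.T @ np.where(obs, x0, 0.0)  # Q x J expected correct
    return post, nq, rq, loglik


def _q_value(nodes, a, d, nq, rq):
    p = expit(np.outer(nodes, a) + d)
    p = np.clip(p, 1e-10, 1.0 - 1e-10)
    return np.sum(rq * np.log(p) + (nq - rq) * np.log1p(-p), axis=0)


def _mstep_2pl(nodes, a, d, nq, rq, n_newton=5):
    """Safeguarded per-item Newton updates of (a, d), vectorized over items."""
    for _ in range(n_newton):
        p = expit(np.outer(nodes, a) + d)
        resid = rq - nq * p
        w = nq * p * (1.0 - p)
        g_a = nodes @ resid
        g_d = resid.sum(axis=0)
        h_aa = (nodes ** 2) @ w
        h_ad = nodes @ w
        h_dd = w.sum(axis=0)
        det = h_aa * h_dd - h_ad ** 2
        det = np.where(det < 1e-12, 1e-12, det)
        da = (h_dd * g_a - h_ad * g_d) / det
        dd = (h_aa * g_d - h_ad * g_a) / det
        f0 = _q_value(nodes, a, d, nq, rq)
        step = np.ones_like(a)
        for _half in range(20):
            f1 = _q_value(nodes, a + step * da, d + step * dd, nq, rq)
            bad = f1 < f0 - 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        a = np.clip(a + step * da, -A_MAX, A_MAX)
        d = np.clip(d + step * dd, -D_MAX, D_MAX)
    return a, d


def _mstep_1pl(nodes, a_common, d, nq, rq):
    """Alternate Newton updates: per-item intercepts, then the common slope."""
    for _ in range(3):
        p = expit(a_common * nodes[:, None] + d)
        resid = rq - nq * p
        w = nq * p * (1.0 - p)
        dd = resid.sum(axis=0) / np.maximum(w.sum(axis=0), 1e-12)
        d = np.clip(d + np.clip(dd, -1.0, 1.0), -D_MAX, D_MAX)
        p = expit(a_common * nodes[:, None] + d)
        g = float(np.sum(nodes[:, None] * (rq - nq * p)))
        h = float(np.sum((nodes ** 2)[:, None] * nq * p * (1.0 - p)))
        a_common = np.clip(a_common + np.clip(g / max(h, 1e-12), -1.0, 1.0),
                           -A_MAX, A_MAX)
    return a_common, d


_BETA_PRIOR = (2.0, 10.0)  # stabilizing prior on the 3PL guessing asymptote


def _mstep_3pl(nodes, a, d, u, nq, rq):
    """Per-item L-BFGS on (a, d, logit c) with the Beta prior on c."""
    alpha, beta = _BETA_PRIOR
    for j in range(len(a)):
        nqj, rqj = nq[:, j], rq[:, j]

        def negq(t):
            aa, dd, uu = t
            cc = expit(uu)
            s = expit(aa * nodes + dd)
            p = np.clip(cc + (1 - cc) * s, 1e-10, 1 - 1e-10)
            val = np.sum(rqj * np.log(p) + (nqj - rqj) * np.log1p(-p))
            val += (alpha - 1) * np.log(cc) + (beta - 1) * np.log1p(-cc)
            # gradient
            dfdp = rqj / p - (nqj - rqj) / (1 - p)
            ds = s * (1 - s)
            ga = np.sum(dfdp * (1 - cc) * ds * nodes)
            gd = np.sum(dfdp * (1 - cc) * ds)
            gc = np.sum(dfdp * (1 - s))
            gc += (alpha - 1) / cc - (beta - 1) / (1 - cc)
            gu = gc * cc * (1 - cc)
            return -val, -np.array([ga, gd, gu])

        res = minimize(negq, np.array([a[j], d[j], u[j]]), jac=True,
                       method="L-BFGS-B",
                       bounds=[(-A_MAX, A_MAX), (-D_MAX, D_MAX), (-6.0, 2.0)],
                       options={"maxiter": 50})
        a[j], d[j], u[j] = res.x
    return a, d, u


def fit_irt(
    responses,
    model: str = "2PL",
    n_quadrature: int = 61,
    tol: float = 1e-5,
    max_iter: int = 2000,
) -> IrtFit:
    """Fit a 1PL/2PL/3PL model by MML-EM under a N(0, 1) ability prior.

    Missing responses are ignored in the item likelihoods.  Items answered
    entirely correctly or entirely incorrectly are dropped with a warning:
    their parameters are unidentified.  Convergence is declared when the
    largest parameter change falls below ``tol``.
    """
    if model not in ("1PL", "2PL", "3PL"):
        raise ValueError(f"unknown model {model!r}")
    x, obs, items = _prep_responses(responses)
    n, n_items_in = x.shape
    if n == 0 or n_items_in == 0:
        raise ValueError("empty response matrix")

    means = np.nansum(np.where(obs, x, 0.0), axis=0) / np.maximum(obs.sum(axis=0), 1)
    degenerate = (means <= 0.0) | (means >= 1.0)
    dropped = [items[j] for j in np.flatnonzero(degenerate)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} item(s) with all-correct or all-incorrect "
            f"responses (parameters unidentified): {dropped[:8]}",
            stacklevel=2,
        )
        keep = ~degenerate
        x, obs = x[:, keep], obs[:, keep]
        items = [it for it, k in zip(items, keep) if k]
    n_items = len(items)
    if n_items == 0:
        raise ValueError("no identifiable items left")

    nodes, weights = _gh_nodes(n_quadrature)
    means = np.clip(
        np.nansum(np.where(obs, x, 0.0), axis=0) / obs.sum(axis=0), 0.01, 0.99
    )
    a = np.ones(n_items)
    d = np.log(means / (1 - means))
    u = np.full(n_items, np.log(0.15 / 0.85))  # logit of a mild guessing start
    a_common = 1.0

    trace = []
    prev = None
    converged = False
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        c = expit(u) if model == "3PL" else 0.0
        slope = np.full(n_items, a_common) if model == "1PL" else a
        _, nq, rq, loglik = _estep(x, obs, nodes, weights, slope, d, c)
        trace.append(loglik)
        old = (slope.copy(), d.copy(), expit(u) if model == "3PL" else None)
        if model == "2PL":
            a, d = _mstep_2pl(nodes, a, d, nq, rq)
            new = (a, d, None)
        elif model == "1PL":
            a_common, d = _mstep_1pl(nodes, a_common, d, nq, rq)
            new = (np.full(n_items, a_common), d, None)
        else:
            a, d, u = _mstep_3pl(nodes, a, d, u, nq, rq)
            new = (a, d, expit(u))
        change = max(
            float(np.max(np.abs(new[0] - old[0]))),
            float(np.max(np.abs(new[1] - old[1]))),
            float(np.max(np.abs(new[2] - old[2]))) if model == "3PL" else 0.0,
        )
        if prev is not None and change < tol:
            converged = True
            break
        prev = loglik

    c = expit(u) if model == "3PL" else np.zeros(n_items)
    slope = np.full(n_items, a_common) if model == "1PL" else a
    _, nq, rq, loglik = _estep(x, obs, nodes, weights, slope, d, c)
    trace.append(loglik)
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations "
            f"(last max parameter change {change:.2e})",
            stacklevel=2,
        )

    # Standard errors from the expected-count information of the final
    # M-step objective (a block-diagonal approximation across items).
    p = expit(np.outer(nodes, slope) + d)
    w = nq * p * (1.0 - p)
    h_aa = (nodes ** 2) @ w
    h_ad = nodes @ w
    h_dd = w.sum(axis=0)
    det = np.maximum(h_aa * h_dd - h_ad ** 2, 1e-12)
    var_a = h_dd / det
    var_d = h_aa / det
    cov_ad = -h_ad / det
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(np.abs(slope) > 1e-8, -d / slope, np.nan)
        # delta method for b = -d/a
        var_b = (d ** 2 * var_a / slope ** 4
                 + var_d / slope ** 2
                 + 2 * d * cov_ad / slope ** 3)
        se_b = np.where(np.abs(slope) > 1e-8, np.sqrt(np.abs(var_b)), np.nan)

    params = pd.DataFrame(
        {
            "a": slope,
            "b": b,
            "c": c,
            "d": d,
            "se_a": np.sqrt(var_a),
            "se_b": se_b,
        },
        index=pd.Index(items, name="item_id"),
    )
    return IrtFit(
        model=model,
        params=params,
        loglik=loglik,
        n_subjects=n,
        n_items=n_items,
        n_quadrature=n_quadrature,
        converged=converged,
        n_iter=it,
        final_change=change,
        loglik_trace=np.asarray(trace),
        dropped_items=dropped,
    )


def icc(params: pd.DataFrame, theta_grid: np.ndarray = DEFAULT_GRID) -> pd.DataFrame:
    """Item characteristic curves P(theta), items x grid."""
    if "d" in params.columns:
        lin = np.outer(params["a"].to_numpy(), theta_grid) + params["d"].to_numpy()[:, None]
    else:
        a = params["a"].to_numpy()[:, None]
        b = params["b"].to_numpy()[:, None]
        lin = a * (theta_grid - b)
    c = params.get("c", pd.Series(0.0, index=params.index)).to_numpy()[:, None]
    return pd.DataFrame(c + (1 - c) * expit(lin), index=params.index,
                        columns=theta_grid)


def item_information(params: pd.DataFrame,
                     theta_grid: np.ndarray = DEFAULT_GRID) -> pd.DataFrame:
    """Fisher information curves; a^2 P(1-P) for the 2PL, the standard
    guessing-corrected form a^2 (1-P)/P ((P-c)/(1-c))^2 for the 3PL."""
    p = icc(params, theta_grid).to_numpy()
    a = params["a"].to_numpy()[:, None]
    c = params.get("c", pd.Series(0.0, index=params.index)).to_numpy()[:, None]
    p = np.clip(p, 1e-12, 1 - 1e-12)
    info = a ** 2 * (1 - p) / p * ((p - c) / (1 - c)) ** 2
    return pd.DataFrame(info, index=params.index, columns=theta_grid)


def eap_scores(params: pd.DataFrame, responses,
               n_quadrature: int = 61) -> pd.DataFrame:
    """Expected a posteriori abilities and posterior SDs under N(0, 1).

    Subjects with no observed responses get the prior mean 0 and SD 1.
    """
    x, obs, items = _prep_responses(responses)
    par = params.loc[items] if set(items) <= set(params.index) else params
    nodes, weights = _gh_nodes(n_quadrature)
    a = par["a"].to_numpy()
    if "d" in par.columns:
        d = par["d"].to_numpy()
    else:
        d = -par["a"].to_numpy() * par["b"].to_numpy()
    c = par.get("c", pd.Series(0.0, index=par.index)).to_numpy()
    p = np.clip(c + (1 - c) * expit(np.outer(nodes, a) + d), 1e-10, 1 - 1e-10)
    x0 = np.where(obs, x, 0.0)
    ll = x0 @ np.log(p).T + (obs & (x0 == 0.0)) @ np.log1p(-p).T
    ll += np.log(weights)
    mx = ll.max(axis=1, keepdims=True)
    post = np.exp(ll - mx)
    post /= post.sum(axis=1, keepdims=True)
    mean = post @ nodes
    sd = np.sqrt(np.maximum(post @ nodes ** 2 - mean ** 2, 0.0))
    index = responses.index if isinstance(responses, pd.DataFrame) else None
    return pd.DataFrame({"theta": mean, "theta_sd": sd}, index=index)


# ---------------------------------------------------------------------------
# three-stage item reduction


@dataclass
class ReductionConfig:
    """Thresholds of the three-stage shortening procedure.

    ``flat_epsilon``: maximum grid information below which a curve counts
    as completely flat.  ``info_threshold``: minimum peak information an
    item must reach to survive stage 2.  ``difficulty_range``: acceptable
    difficulty window on the N(0, 1) ability scale.  ``redundancy_distance``:
    sup-norm ICC distance under which two items count as identical.
    ``flat_icc_rise``: minimum total rise of the ICC over the grid for the
    curve to count as discriminating in stage 3.  ``stage3_domains``: the
    domains whose battery is refined down to ``quota_per_domain`` items.
    """

    flat_epsilon: float = 0.02
    info_threshold: float = 0.2
    difficulty_range: tuple[float, float] = (-3.0, 3.0)
    redundancy_distance: float = 0.02
    flat_icc_rise: float = 0.1
    quota_per_domain: int = 20
    stage3_domains: tuple[str, ...] = ("verbal",)
    theta_grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())


def reduce_items(
    fit: IrtFit,
    domains: pd.Series,
    config: ReductionConfig | None = None,
) -> pd.DataFrame:
    """Run the three-stage reduction; returns the per-item selection report.

    The report has one row per calibrated item with its removal stage
    (``kept``, ``stage1_flat``, ``stage2_low_info``, ``stage2_out_of_range``,
    ``stage3_low_info``, ``stage3_flat_icc``, ``stage3_redundant``), peak
    information and difficulty.  Stage 3 refines only the configured
    domains; removal priority is flat characteristic curves, then
    redundant curves (first-listed item retained), then lowest peak
    information, stopping as soon as the quota is met.  A domain that
    cannot reach its quota raises an error naming the shortfall.
    """
    cfg = config or ReductionConfig()
    params = fit.params
    domains = domains.reindex(params.index)
    if domains.isna().any():
        missing = list(params.index[domains.isna()])[:5]
        raise ValueError(f"domain labels missing for items: {missing}")

    info = item_information(params, cfg.theta_grid)
    curves = icc(params, cfg.theta_grid)
    peak = info.max(axis=1)
    status = pd.Series("kept", index=params.index, dtype=object)

    # stage 1: completely flat information curves
    status[peak < cfg.flat_epsilon] = "stage1_flat"

    # stage 2: information never reaching the threshold, or difficulty
    # outside the target range (too easy / too hard)
    alive = status == "kept"
    lo, hi = cfg.difficulty_range
    b = params["b"]
    out_of_range = alive & (b.isna() | (b < lo) | (b > hi))
    low_info = alive & ~out_of_range & (peak < cfg.info_threshold)
    status[low_info] = "stage2_low_info"
    status[out_of_range] = "stage2_out_of_range"

    # stage 3: per-domain refinement to the quota
    for domain in cfg.stage3_domains:
        members = [it for it in params.index
                   if domains[it] == domain and status[it] == "kept"]
        n_excess = len(members) - cfg.quota_per_domain
        if n_excess < 0:
            raise ValueError(
                f"domain {domain!r}: only {len(members)} items survive stages "
                f"1-2, {cfg.quota_per_domain - len(members)} short of the quota"
            )
        if n_excess == 0:
            continue
        removed = 0
        # (a) flat characteristic curves: almost no rise over the grid
        rise = curves.loc[members].to_numpy()
        rise = rise.max(axis=1) - rise.min(axis=1)
        for it, r in zip(list(members), rise):
            if removed >= n_excess:
                break
            if r < cfg.flat_icc_rise:
                status[it] = "stage3_flat_icc"
                members.remove(it)
                removed += 1
        # (b) redundant curves: sup-norm within the tolerance of an earlier
        # (first-listed, hence retained) item; removal proceeds from the
        # end of the list so ties break in favour of item order
        reps: list[str] = []
        duplicates: list[str] = []
        for it in members:
            cur = curves.loc[it].to_numpy()
            dup = any(
                np.max(np.abs(cur - curves.loc[rep].to_numpy()))
                < cfg.redundancy_distance
                for rep in reps
            )
            (duplicates if dup else reps).append(it)
        for it in reversed(duplicates):
            if removed >= n_excess:
                break
            status[it] = "stage3_redundant"
            members.remove(it)
            removed += 1
        # (c) least informative items until the quota is met
        while removed < n_excess:
            worst = peak[members].idxmin()
            status[worst] = "stage3_low_info"
            members.remove(worst)
            removed += 1

    report = pd.DataFrame(
        {
            "domain": domains,
            "stage": status,
            "peak_information": peak,
            "a": params["a"],
            "b": params["b"],
        }
    )
    report.index.name = "item_id"
    return report
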