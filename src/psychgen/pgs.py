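"""SNP heritability and polygenic-score prediction.

The genetic relationship matrix (GRM) averages allele-frequency
standardized genotype cross-products over SNPs; its off-diagonal entries
estimate genome-wide relatedness.  SNP heritability is estimated by
restricted maximum likelihood on y = g + e with V = sigma_g^2 A +
sigma_e^2 I, using average-information (AI) updates with EM fallback
steps.  Because A enters V linearly, a single eigendecomposition of the
GRM turns every REML quantity into O(n) diagonal arithmetic per
iteration, which keeps thousand-individual fits fast without
approximation.

Polygenic weights follow the infinitesimal-prior posterior mean: within
each LD window, beta_tilde = (M/(N h^2) I + D)^-1 beta_hat, where D is
the local LD correlation matrix from the target genotypes; with no LD
this reduces to uniform shrinkage beta_hat / (1 + M/(N h^2)).  Scores
are dosage-weighted sums, and prediction is summarized as incremental
R^2: the variance explained by covariates plus score minus the variance
explained by covariates alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from ._types import GenotypeMatrix

__all__ = [
    "compute_grm",
    "prune_related",
    "greml",
    "GremlResult",
    "ldpred_inf",
    "score_and_r2",
    "combine_scores",
]


# ---------------------------------------------------------------------------
# GRM


@dataclass
class Grm:
    ids: list[str]
    matrix: np.ndarray
    n_snps: np.ndarray  # per-pair count of SNPs used (lower triangle meaningful)

    @property
    def n(self) -> int:
        return len(self.ids)


def compute_grm(genotypes: GenotypeMatrix, maf_min: float = 0.01) -> Grm:
    """GCTA-style GRM: A_jk = (1/M) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i)).

    Allele frequencies are recomputed from the sample.  SNPs with MAF
    below ``maf_min`` are excluded; a monomorphic SNP surviving the filter
    is an error.
    """
    dose = genotypes.dosages
    p = dose.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf > maf_min
    if not keep.any():
        raise ValueError("no SNPs left after MAF filtering")
    p = p[keep]
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic SNP encountered after QC")
    z = (dose[:, keep] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = int(keep.sum())
    a = z @ z.T / m
    a = (a + a.T) / 2.0
    counts = np.full((genotypes.n, genotypes.n), m, dtype=np.int64)
    return Grm(ids=list(genotypes.ids), matrix=a, n_snps=counts)


def prune_related(grm: Grm, threshold: float = 0.05) -> list[str]:
    """Greedy relatedness pruning to a maximum off-diagonal relatedness.

    While any off-diagonal entry exceeds the threshold, the individual
    involved in the most over-threshold pairs is removed (ties broken by
    first id).  Returns the retained ids; no retained pair exceeds the
    threshold.
    """
    a = grm.matrix.copy()
    np.fill_diagonal(a, 0.0)
    alive = np.ones(grm.n, dtype=bool)
    while True:
        over = (a > threshold) & alive[:, None] & alive[None, :]
        if not over.any():
            break
        counts = over.sum(axis=1)
        worst = int(np.argmax(counts))  # argmax takes the first maximum
        alive[worst] = False
    return [i for i, keep in zip(grm.ids, alive) if keep]


# ---------------------------------------------------------------------------
# AI-REML


@dataclass
class GremlResult:
    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    loglik_trace: list = field(default_factory=list)
    n_used: int = 0
    n_iter: int = 0
    converged: bool = False


class _RemlWorkspace:
    """REML quantities for V = s_g A + s_e I in the GRM eigenbasis."""

    def __init__(self, y: np.ndarray, grm_matrix: np.ndarray,
                 x: np.ndarray | None):
        lam, u = np.linalg.eigh(grm_matrix)
        self.lam = np.clip(lam, 0.0, None)
        self.yt = u.T @ y
        self.n = len(y)
        if x is None:
            x = np.ones((self.n, 1))
        self.xt = u.T @ x
        self.p = x.shape[1]

    def _core(self, sg: float, se: float):
        d = sg * self.lam + se
        if np.any(d <= 0):
            return None
        dinv = 1.0 / d
        xtd = self.xt * dinv[:, None]
        xvx = self.xt.T @ xtd
        xvx_inv = np.linalg.inv(xvx)
        beta = xvx_inv @ (xtd.T @ self.yt)
        resid = self.yt - self.xt @ beta
        py = resid * dinv  # P y in the eigenbasis
        return d, dinv, xtd, xvx, xvx_inv, py

    def loglik(self, sg: float, se: float) -> float:
        core = self._core(sg, se)
        if core is None:
            return -np.inf
        d, _, _, xvx, xvx_inv, _ = core
        _, logdet_xvx = np.linalg.slogdet(xvx)
        beta = xvx_inv @ ((self.xt * (1.0 / d)[:, None]).T @ self.yt)
        resid = self.yt - self.xt @ beta
        ypy = float(resid @ (resid / d))
        return -0.5 * (float(np.sum(np.log(d))) + logdet_xvx + ypy)

    def derivatives(self, sg: float, se: float):
        """REML gradient and AI matrix for (sigma_g^2, sigma_e^2)."""
        core = self._core(sg, se)
        if core is None:
            raise FloatingPointError("V not positive definite")
        d, dinv, xtd, xvx, xvx_inv, py = core

        def p_dot(v):
            """Apply the projection P to a vector in the eigenbasis."""
            tmp = v * dinv
            return tmp - xtd @ (xvx_inv @ (self.xt.T @ tmp))

        py = p_dot(self.yt)
        apy = self.lam * py
        papy = p_dot(apy)
        ppy = p_dot(py)

        # tr(P A) = tr(D^-1 A) - tr((X'V^-1X)^-1 X'V^-1 A V^-1 X)
        tr_pa = float(np.sum(self.lam * dinv)) - float(
            np.trace(xvx_inv @ (xtd.T @ (self.lam[:, None] * xtd))))
        tr_p = float(np.sum(dinv)) - float(np.trace(xvx_inv @ (xtd.T @ xtd)))

        ypay = float(py @ apy)
        ypy = float(py @ py)
        grad = np.array([
            -0.5 * (tr_pa - ypay),
            -0.5 * (tr_p - ypy),
        ])
        ai = 0.5 * np.array([
            [float(apy @ papy), float(apy @ ppy)],
            [float(apy @ ppy), float(py @ ppy)],
        ])
        em_terms = np.array([ypay - tr_pa, ypy - tr_p])
        return grad, ai, em_terms


def greml(
    phenotype: np.ndarray | pd.Series,
    grm: Grm,
    covariates: np.ndarray | pd.DataFrame | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> GremlResult:
    """SNP heritability by AI-REML on V = sigma_g^2 A + sigma_e^2 I.

    The phenotype is standardized internally; a fixed intercept (plus any
    covariates) is absorbed by the REML projection.  AI updates that leave
    the parameter space fall back to EM steps; variance components are
    floored at a small positive value.  The heritability standard error
    comes from the inverse AI matrix by the delta method.
    """
    if isinstance(phenotype, pd.Series):
        y = phenotype.to_numpy(float)
    else:
        y = np.asarray(phenotype, float)
    if len(y) != grm.n:
        raise ValueError("phenotype length does not match GRM")
    y = (y - y.mean()) / y.std()
    x = None
    if covariates is not None:
        c = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) \
            else np.asarray(covariates, float)
        x = np.column_stack([np.ones(len(y)), c])
    ws = _RemlWorkspace(y, grm.matrix, x)

    var_y = 1.0
    sg, se = 0.5 * var_y, 0.5 * var_y
    floor = 1e-6 * var_y
    trace = [ws.loglik(sg, se)]
    converged = False
    it = 0
    ai = np.eye(2)
    for it in range(1, max_iter + 1):
        grad, ai, em_terms = ws.derivatives(sg, se)
        try:
            step = np.linalg.solve(ai, grad)
        except np.linalg.LinAlgError:
            step = None
        new = None
        if step is not None:
            cand = np.array([sg, se]) + step
            if np.all(cand > floor):
                new = cand
        if new is None:
            # EM fallback: sigma_i^2 <- sigma_i^2 + sigma_i^4 / n * (y'P Vi P y - tr(P Vi))
            cand = np.array([sg, se]) + np.array([sg ** 2, se ** 2]) / ws.n * em_terms
            new = np.maximum(cand, floor)
        new_ll = ws.loglik(*new)
        # step-halve towards the current point if the likelihood got worse
        tries = 0
        while new_ll < trace[-1] - 1e-8 and tries < 20:
            new = (new + np.array([sg, se])) / 2.0
            new_ll = ws.loglik(*new)
            tries += 1
        change = abs(new_ll - trace[-1])
        sg, se = float(new[0]), float(new[1])
        trace.append(new_ll)
        if change < tol:
            converged = True
            break
    if not converged:
        # AI steps can stall on very small samples; polish with a direct
        # bounded search of the restricted likelihood (cheap in the
        # eigenbasis) before giving up
        from scipy.optimize import minimize

        res = minimize(lambda t: -ws.loglik(*np.exp(t)),
                       np.log([max(sg, floor), max(se, floor)]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        if -res.fun >= trace[-1]:
            sg, se = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
            trace.append(-res.fun)
            converged = res.success
    if not converged:
        warnings.warn(f"AI-REML did not converge in {max_iter} iterations",
                      stacklevel=2)

    h2 = sg / (sg + se)
    try:
        _, ai, _ = ws.derivatives(sg, se)
        cov = np.linalg.inv(ai)
        total = sg + se
        grad_h2 = np.array([se, -sg]) / total ** 2
        se_h2 = float(np.sqrt(grad_h2 @ cov @ grad_h2))
    except (np.linalg.LinAlgError, FloatingPointError):
        se_h2 = np.nan
    return GremlResult(sigma2_g=sg, sigma2_e=se, h2=float(h2), se_h2=se_h2,
                       loglik_trace=trace, n_used=grm.n, n_iter=it,
                       converged=converged)


# ---------------------------------------------------------------------------
# LDpred-infinitesimal weights


def ldpred_inf(
    sumstats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    h2: float,
    n_gwas: int | None = None,
    window: int = 100,
    overlap: int = 50,
) -> pd.DataFrame:
    """Infinitesimal-prior posterior-mean weights with windowed LD solves.

    ``sumstats`` must already be harmonized to ``genotypes`` (same SNPs,
    same counted allele; see ``io.read_sumstats``).  Within each sliding
    window the weights solve (M/(N h^2) I + D) beta_tilde = beta_hat with
    D the window's LD correlation matrix from the target genotypes;
    overlapping solutions are averaged.  Returns a weight table with
    standardized-scale and dosage-scale columns.
    """
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    order = {s: i for i, s in enumerate(genotypes.snps["snp"])}
    if not set(sumstats["SNP"]) <= set(order):
        missing = sorted(set(sumstats["SNP"]) - set(order))[:5]
        raise ValueError(f"sumstats SNPs absent from genotypes: {missing}")
    ss = sumstats.sort_values("SNP", key=lambda s: s.map(order)).reset_index(drop=True)
    idx = ss["SNP"].map(order).to_numpy()
    beta_hat = ss["BETA"].to_numpy(float)
    n = int(n_gwas) if n_gwas is not None else int(ss["N"].median())
    m = len(beta_hat)
    ridge = m / (n * h2)

    dose = genotypes.dosages[:, idx]
    p = dose.mean(axis=0) / 2.0
    # empirical standardization, so D is exactly the sample correlation
    sd = dose.std(axis=0)
    if np.any(sd == 0):
        bad = ss["SNP"][sd == 0].tolist()[:5]
        raise ValueError(f"monomorphic SNPs in the LD reference: {bad}")
    z = (dose - dose.mean(axis=0)) / sd

    beta_sum = np.zeros(m)
    counts = np.zeros(m)
    step = max(window - overlap, 1)
    start = 0
    while start < m:
        stop = min(start + window, m)
        zw = z[:, start:stop]
        d_w = zw.T @ zw / z.shape[0]
        lhs = ridge * np.eye(stop - start) + d_w
        beta_sum[start:stop] += np.linalg.solve(lhs, beta_hat[start:stop])
        counts[start:stop] += 1
        if stop == m:
            break
        start += step
    beta_tilde = beta_sum / counts
    return pd.DataFrame(
        {
            "SNP": ss["SNP"].to_numpy(),
            "A1": ss["A1"].to_numpy(),
            "A2": ss["A2"].to_numpy(),
            "beta_std": beta_tilde,
            "beta_dose": beta_tilde / sd,
            "freq": p,
        }
    )


# ---------------------------------------------------------------------------
# scoring and incremental R^2


def polygenic_score(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> pd.Series:
    """Per-individual dosage-weighted sum over the SNPs in the weight table."""
    order = {s: i for i, s in enumerate(genotypes.snps["snp"])}
    idx = weights["SNP"].map(order)
    if idx.isna().any():
        missing = weights["SNP"][idx.isna()].tolist()[:5]
        raise ValueError(f"weight SNPs absent from genotypes: {missing}")
    dose = genotypes.dosages[:, idx.to_numpy(int)]
    score = dose @ weights["beta_dose"].to_numpy(float)
    return pd.Series(score, index=genotypes.ids, name="gps")


def _ols(y: np.ndarray, x: np.ndarray):
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    resid = y - fitted
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else 0.0
    return coef, resid, r2


def score_and_r2(
    phenotype: pd.Series | np.ndarray,
    scores: pd.DataFrame | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Incremental R^2 of each polygenic score over the covariate model.

    Phenotype, scores and covariates are standardized before regression.
    For each score: delta R^2 = R^2(covariates + score) - R^2(covariates),
    with the score's regression coefficient, SE and t statistic from the
    full model.  Delta R^2 is non-negative by construction (the covariate
    model is nested in the full model).
    """
    y = np.asarray(phenotype, float)
    y = (y - y.mean()) / y.std()
    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    n = len(y)
    if covariates is None:
        cov = np.ones((n, 1))
    else:
        c = covariates.to_numpy(float) if hasattr(covariates, "to_numpy") \
            else np.asarray(covariates, float)
        c = (c - c.mean(axis=0)) / np.where(c.std(axis=0) == 0, 1.0, c.std(axis=0))
        cov = np.column_stack([np.ones(n), c])
    _, _, r2_null = _ols(y, cov)

    rows = []
    for name in scores.columns:
        s = scores[name].to_numpy(float)
        sd = s.std()
        s = (s - s.mean()) / sd if sd > 0 else s - s.mean()
        x_full = np.column_stack([cov, s])
        coef, resid, r2_full = _ols(y, x_full)
        dof = n - x_full.shape[1]
        sigma2 = float(resid @ resid) / max(dof, 1)
        xtx_inv = np.linalg.pinv(x_full.T @ x_full)
        se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        beta = float(coef[-1])
        rows.append({
            "score": name,
            "delta_r2": max(r2_full - r2_null, 0.0),
            "beta": beta,
            "se": se,
            "t": beta / se if se > 0 else np.nan,
            "r2_full": r2_full,
            "r2_null": r2_null,
        })
    return pd.DataFrame(rows).set_index("score")


def combine_scores(
    phenotype: pd.Series,
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    train_fraction: float = 0.5,
    seed: int = 0,
) -> dict:
    """Multi-score combination: joint OLS weights in a training split,
    incremental R^2 of the combined score in the holdout.

    A near-collinear score set is reported and handled with a small ridge
    penalty on the training regression.
    """
    rng = np.random.default_rng(seed)
    n = len(phenotype)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train, hold = perm[:n_train], perm[n_train:]
    y = np.asarray(phenotype, float)
    y = (y - y.mean()) / y.std()
    s = scores.to_numpy(float)
    s = (s - s.mean(axis=0)) / s.std(axis=0)

    x_tr = np.column_stack([np.ones(len(train)), s[train]])
    xtx = x_tr.T @ x_tr
    collinear = np.linalg.cond(xtx) > 1e10
    if collinear:
        warnings.warn("collinear score set; applying ridge fallback",
                      stacklevel=2)
        xtx = xtx + 1e-6 * np.trace(xtx) / xtx.shape[0] * np.eye(xtx.shape[0])
    w = np.linalg.solve(xtx, x_tr.T @ y[train])
    combined = s @ w[1:]

    hold_res = score_and_r2(
        pd.Series(y[hold]),
        pd.DataFrame({"combined": combined[hold]}),
        covariates.iloc[hold] if covariates is not None else None,
    )
    return {
        "weights": dict(zip(scores.columns, w[1:])),
        "collinear": bool(collinear),
        "holdout": hold_res.loc["combined"].to_dict(),
        "combined_score": pd.Series(combined, index=scores.index
                                    if hasattr(scores, "index") else None),
    }
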