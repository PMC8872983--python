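"""Classical twin analysis.

The variance of a standardized trait is decomposed into additive genetic
(A), shared environmental (C) and nonshared environmental (E) parts by
comparing monozygotic pairs (who share all segregating variants) with
dizygotic pairs (who share half on average).  Under the ACE model the
expected cross-twin covariance is a^2 + c^2 for MZ and 0.5 a^2 + c^2 for
DZ pairs.  The module provides method-of-moments (Falconer) estimates,
full-information ML fits with saturated-model comparison and profile or
bootstrap confidence intervals, the bivariate Cholesky decomposition of a
cross-trait correlation, and five-group sex-limitation models.

Traits are standardized (grand mean/SD over all twin values) before
fitting and means are fixed at zero, so the fitted components are on the
standardized scale directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.stats import chi2

from ._types import TwinDataset

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# correlations and Falconer estimates


def double_entry_corr(pairs: np.ndarray) -> float:
    """Intraclass correlation by double entry (both twin orderings)."""
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return float(np.corrcoef(x, y)[0, 1])


def twin_correlations(
    data: TwinDataset,
    trait: str | None = None,
    grouping: str = "zygosity",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group double-entry intraclass correlations with bootstrap CIs.

    ``grouping`` is ``"zygosity"`` (MZ vs DZ) or ``"zygosity_by_sex"``
    (MZm, MZf, DZm, DZf, DZos).  Groups with fewer than three pairs are
    skipped with a warning row (r = NaN).
    """
    if grouping not in ("zygosity", "zygosity_by_sex"):
        raise ValueError(f"unknown grouping {grouping!r}")
    trait = trait or data.traits[0]
    col = "zygosity" if grouping == "zygosity" else "group"
    rng = np.random.default_rng(seed)
    rows = []
    for label in data.pairs[col].unique():
        kwargs = {"zygosity": label} if col == "zygosity" else {"group": label}
        pairs = data.trait_pairs(trait, **kwargs)
        n = len(pairs)
        if n < 3:
            rows.append({"group": label, "n_pairs": n, "r": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        r = double_entry_corr(pairs)
        boots = np.empty(n_boot)
        for bi in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[bi] = double_entry_corr(pairs[idx])
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        rows.append({"group": label, "n_pairs": n, "r": r,
                     "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows).set_index("group")


def falconer(r_mz: float, r_dz: float) -> dict:
    """Method-of-moments ACE estimates from twin intraclass correlations.

    a2 = 2 (rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ.  Components that
    fall outside [0, 1] are returned untruncated with ``out_of_bounds``
    set, so callers can see boundary evidence rather than silently losing it.
    """
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    e2 = 1.0 - r_mz
    out = not all(0.0 <= v <= 1.0 for v in (a2, c2, e2))
    return {"a2": a2, "c2": c2, "e2": e2, "out_of_bounds": out}


# ---------------------------------------------------------------------------
# univariate ML ACE


def _suff_stats(pairs: np.ndarray) -> tuple[int, np.ndarray]:
    """Pair count and second-moment matrix about zero."""
    n = len(pairs)
    return n, pairs.T @ pairs / n


def _neg2ll_gauss(n: int, s: np.ndarray, sigma: np.ndarray) -> float:
    """-2 log likelihood of n zero-mean Gaussian vectors with moment matrix s."""
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    return n * (sigma.shape[0] * _LOG2PI + logdet
                + float(np.trace(np.linalg.solve(sigma, s))))


def _ace_cov(a: float, c: float, e: float, kin: float) -> np.ndarray:
    v = a * a + c * c + e * e
    cov = kin * a * a + c * c
    return np.array([[v, cov], [cov, v]])


def _standardize(values: np.ndarray) -> np.ndarray:
    mu, sd = np.nanmean(values), np.nanstd(values)
    if sd == 0:
        raise ValueError("trait has zero variance")
    return (values - mu) / sd


@dataclass
class AceResult:
    """Univariate fit: standardized components, CIs and model comparisons."""

    a2: float
    c2: float
    e2: float
    ci: dict[str, tuple[float, float]]
    neg2ll: float
    neg2ll_saturated: float
    chi2_vs_saturated: float
    df_vs_saturated: int
    p_vs_saturated: float
    submodels: dict[str, dict] = field(default_factory=dict)
    boundary: list[str] = field(default_factory=list)
    n_mz: int = 0
    n_dz: int = 0

    @property
    def estimates(self) -> tuple[float, float, float]:
        return self.a2, self.c2, self.e2


def _fit_paths(
    n_mz, s_mz, n_dz, s_dz, free: str = "ace", n_starts: int = 5, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Minimize -2LL over path coefficients; fixed-at-zero paths per submodel."""
    rng = np.random.default_rng(seed)
    mask = np.array([ch in free for ch in "ace"])

    def unpack(x):
        full = np.zeros(3)
        full[mask] = x
        return full

    def obj(x):
        a, c, e = unpack(x)
        if abs(e) < 1e-6:
            e = 1e-6
        return (_neg2ll_gauss(n_mz, s_mz, _ace_cov(a, c, e, 1.0))
                + _neg2ll_gauss(n_dz, s_dz, _ace_cov(a, c, e, 0.5)))

    best_x, best_f = None, np.inf
    base = np.array([0.6, 0.3, 0.6])[mask]
    for k in range(n_starts):
        x0 = base if k == 0 else np.abs(base + 0.3 * rng.standard_normal(mask.sum()))
        res = minimize(obj, x0, method="L-BFGS-B",
                       bounds=[(0.0, 2.0)] * int(mask.sum()))
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
    return unpack(best_x), best_f


def _saturated_neg2ll(groups: list[tuple[int, np.ndarray]]) -> float:
    """Zero-mean saturated model: free covariance matrix per group."""
    total = 0.0
    for n, s in groups:
        total += _neg2ll_gauss(n, s, s)
    return total


def fit_ace(
    data: TwinDataset,
    trait: str | None = None,
    submodels: tuple[str, ...] = ("AE", "CE", "E"),
    ci_method: str = "profile",
    n_boot: int = 1000,
    seed: int = 0,
) -> AceResult:
    """Full-information ML ACE fit with saturated comparison and 95% CIs.

    Paths are estimated (bounded at zero, so variance components cannot go
    negative); standardized components are the squared paths over their
    sum.  The saturated reference frees each group's covariance matrix.
    Profile-likelihood CIs invert the chi-square(1) threshold on the
    standardized components; ``ci_method="bootstrap"`` resamples pairs.
    """
    trait = trait or data.traits[0]
    mz = data.trait_pairs(trait, zygosity="MZ")
    dz = data.trait_pairs(trait, zygosity="DZ")
    if len(mz) == 0 or len(dz) == 0:
        raise ValueError("both MZ and DZ pairs are required")
    allv = np.concatenate([mz.ravel(), dz.ravel()])
    mu, sd = allv.mean(), allv.std()
    if sd == 0:
        raise ValueError("trait has zero variance")
    mz = (mz - mu) / sd
    dz = (dz - mu) / sd
    n_mz, s_mz = _suff_stats(mz)
    n_dz, s_dz = _suff_stats(dz)

    paths, neg2ll = _fit_paths(n_mz, s_mz, n_dz, s_dz, "ace", seed=seed)
    comps = paths ** 2
    total = comps.sum()
    a2, c2, e2 = comps / total
    boundary = [name for name, v in zip(("a2", "c2", "e2"), (a2, c2, e2))
                if v < 1e-6]

    sat = _saturated_neg2ll([(n_mz, s_mz), (n_dz, s_dz)])
    dchi = max(neg2ll - sat, 0.0)
    df = 6 - 3
    sub = {}
    for name in submodels:
        free = {"AE": "ae", "CE": "ce", "E": "e"}[name]
        sp, sll = _fit_paths(n_mz, s_mz, n_dz, s_dz, free, seed=seed)
        sc = sp ** 2 / (sp ** 2).sum()
        sub[name] = {
            "a2": sc[0], "c2": sc[1], "e2": sc[2],
            "neg2ll": sll,
            "chi2_vs_ace": max(sll - neg2ll, 0.0),
            "df_vs_ace": 3 - len(free),
            "p_vs_ace": float(chi2.sf(max(sll - neg2ll, 0.0), 3 - len(free))),
        }

    if ci_method == "profile":
        ci = _profile_ci(n_mz, s_mz, n_dz, s_dz, (a2, c2, e2), neg2ll)
    elif ci_method == "bootstrap":
        ci = _bootstrap_ci(mz, dz, n_boot, seed)
    elif ci_method == "none":
        ci = {}
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return AceResult(
        a2=float(a2), c2=float(c2), e2=float(e2), ci=ci,
        neg2ll=neg2ll, neg2ll_saturated=sat,
        chi2_vs_saturated=dchi, df_vs_saturated=df,
        p_vs_saturated=float(chi2.sf(dchi, df)),
        submodels=sub, boundary=boundary, n_mz=n_mz, n_dz=n_dz,
    )


def _constrained_neg2ll(n_mz, s_mz, n_dz, s_dz, comp: int, value: float) -> float:
    """Minimum -2LL with one standardized component pinned at ``value``."""

    def obj(x):
        split, scale = x
        rest = 1.0 - value
        other = np.clip(rest * split, 0.0, 1.0)
        third = max(rest - other, 0.0)
        std = np.zeros(3)
        std[comp] = value
        idx = [i for i in range(3) if i != comp]
        std[idx[0]], std[idx[1]] = other, third
        var = np.maximum(std * scale, 0.0)
        a, c, e = np.sqrt(var)
        return (_neg2ll_gauss(n_mz, s_mz, _ace_cov(a, c, e, 1.0))
                + _neg2ll_gauss(n_dz, s_dz, _ace_cov(a, c, e, 0.5)))

    best = np.inf
    for split0 in (0.2, 0.5, 0.8):
        res = minimize(obj, np.array([split0, 1.0]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400})
        best = min(best, float(res.fun))
    return best


def _profile_ci(n_mz, s_mz, n_dz, s_dz, est, neg2ll, level_chi2=3.841) -> dict:
    ci = {}
    target = neg2ll + level_chi2

    for comp, (name, point) in enumerate(zip(("a2", "c2", "e2"), est)):
        def gap(v):
            return _constrained_neg2ll(n_mz, s_mz, n_dz, s_dz, comp, v) - target

        lo = 0.0
        if point > 1e-4 and gap(0.0) > 0:
            lo = brentq(gap, 0.0, point, xtol=1e-4)
        hi = 1.0
        if point < 1.0 - 1e-4 and gap(1.0 - 1e-9) > 0:
            hi = brentq(gap, point, 1.0 - 1e-9, xtol=1e-4)
        ci[name] = (float(lo), float(hi))
    return ci


def _bootstrap_ci(mz, dz, n_boot, seed) -> dict:
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 3))
    for bi in range(n_boot):
        bm = mz[rng.integers(0, len(mz), len(mz))]
        bd = dz[rng.integers(0, len(dz), len(dz))]
        paths, _ = _fit_paths(*_suff_stats(bm), *_suff_stats(bd), "ace",
                              n_starts=1, seed=bi)
        comps = paths ** 2
        draws[bi] = comps / comps.sum()
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    return {name: (float(l), float(h))
            for name, l, h in zip(("a2", "c2", "e2"), lo, hi)}


# ---------------------------------------------------------------------------
# bivariate Cholesky


@dataclass
class BivariateResult:
    """Cross-trait decomposition from the bivariate Cholesky fit."""

    a2: tuple[float, float]
    c2: tuple[float, float]
    e2: tuple[float, float]
    ra: float
    rc: float
    re: float
    r_phenotypic: float
    parts: dict[str, float]        # additive contribution of A/C/E to r_p
    proportions: dict[str, float]  # parts / r_p
    neg2ll: float


def _chol_from_params(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mats = []
    for k in range(3):
        l11, l21, l22 = x[3 * k: 3 * k + 3]
        low = np.array([[l11, 0.0], [l21, l22]])
        mats.append(low @ low.T)
    return tuple(mats)


def _bivariate_sigma(a_m, c_m, e_m, kin: float) -> np.ndarray:
    within = a_m + c_m + e_m
    cross = kin * a_m + c_m
    top = np.hstack([within, cross])
    bot = np.hstack([cross.T, within])
    return np.vstack([top, bot])


def fit_bivariate_ace(
    data: TwinDataset,
    traits: tuple[str, str] | None = None,
    seed: int = 0,
    n_starts: int = 5,
) -> BivariateResult:
    """Bivariate Cholesky ML fit and decomposition of the cross-trait r.

    The 4x4 per-group covariance (twin1 trait1, twin1 trait2, twin2 trait1,
    twin2 trait2) is parameterized through lower-triangular Cholesky
    factors of A, C and E, which keeps every intermediate model covariance
    positive semi-definite.  The phenotypic cross-trait correlation is
    split additively into A, C and E parts: part_X = X12 / sqrt(V1 V2),
    which sum to the model-implied r_p exactly.
    """
    traits = traits or tuple(data.traits[:2])
    if len(traits) != 2:
        raise ValueError("exactly two traits required")
    stacked = {}
    for zyg in ("MZ", "DZ"):
        p1 = data.trait_pairs(traits[0], zygosity=zyg)
        p2 = data.trait_pairs(traits[1], zygosity=zyg)
        stacked[zyg] = np.column_stack([p1[:, 0], p2[:, 0], p1[:, 1], p2[:, 1]])
    # standardize each trait over all twins
    for t_idx in range(2):
        allv = np.concatenate([stacked["MZ"][:, [t_idx, 2 + t_idx]].ravel(),
                               stacked["DZ"][:, [t_idx, 2 + t_idx]].ravel()])
        mu, sd = allv.mean(), allv.std()
        for zyg in ("MZ", "DZ"):
            stacked[zyg][:, [t_idx, 2 + t_idx]] = \
                (stacked[zyg][:, [t_idx, 2 + t_idx]] - mu) / sd
    n_mz, s_mz = _suff_stats(stacked["MZ"])
    n_dz, s_dz = _suff_stats(stacked["DZ"])

    def obj(x):
        a_m, c_m, e_m = _chol_from_params(x)
        e_m = e_m + 1e-8 * np.eye(2)
        return (_neg2ll_gauss(n_mz, s_mz, _bivariate_sigma(a_m, c_m, e_m, 1.0))
                + _neg2ll_gauss(n_dz, s_dz, _bivariate_sigma(a_m, c_m, e_m, 0.5)))

    rng = np.random.default_rng(seed)
    x_base = np.array([0.7, 0.3, 0.6, 0.3, 0.1, 0.3, 0.5, 0.2, 0.5])
    best_x, best_f = None, np.inf
    for k in range(n_starts):
        x0 = x_base if k == 0 else x_base + 0.2 * rng.standard_normal(9)
        res = minimize(obj, x0, method="L-BFGS-B", options={"maxiter": 2000})
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
    a_m, c_m, e_m = _chol_from_params(best_x)

    v = np.diag(a_m + c_m + e_m)
    std = np.sqrt(v[0] * v[1])
    r_p = float((a_m[0, 1] + c_m[0, 1] + e_m[0, 1]) / std)
    parts = {
        "A": float(a_m[0, 1] / std),
        "C": float(c_m[0, 1] / std),
        "E": float(e_m[0, 1] / std),
    }
    prop = {k: (p / r_p if r_p != 0 else np.nan) for k, p in parts.items()}

    def corr(m):
        d = np.sqrt(np.diag(m))
        if np.any(d < 1e-8):
            return np.nan
        return float(m[0, 1] / (d[0] * d[1]))

    return BivariateResult(
        a2=tuple(np.diag(a_m) / v), c2=tuple(np.diag(c_m) / v),
        e2=tuple(np.diag(e_m) / v),
        ra=corr(a_m), rc=corr(c_m), re=corr(e_m),
        r_phenotypic=r_p, parts=parts, proportions=prop, neg2ll=best_f,
    )


# ---------------------------------------------------------------------------
# five-group sex limitation


@dataclass
class SexLimitationResult:
    full_params: dict
    neg2ll_full: float
    neg2ll_common: float       # opposite-sex genetic correlation fixed at 1
    neg2ll_homogeneous: float  # and equal male/female paths
    qualitative: dict          # LRT: full vs common
    quantitative: dict         # LRT: common vs homogeneous
    missing_groups: list[str] = field(default_factory=list)


_FIVE_GROUPS = ("MZm", "MZf", "DZm", "DZf", "DZos")


def fit_sex_limitation(
    data: TwinDataset, trait: str | None = None, seed: int = 0, n_starts: int = 5
) -> SexLimitationResult:
    """Qualitative and quantitative sex-limitation tests on five groups.

    Nested sequence: full model (sex-specific a/c/e paths plus a free
    opposite-sex DZ genetic correlation rg in [0, 1]) -> common-effects
    model (rg = 1, i.e. the usual 0.5-scaled DZ genetic covariance) ->
    homogeneous model (additionally equal male and female paths).  The
    qualitative test compares full vs common (df = 1), the quantitative
    test common vs homogeneous (df = 3).
    """
    trait = trait or data.traits[0]
    present = set(data.pairs["group"].unique())
    missing = [g for g in _FIVE_GROUPS if g not in present]
    if missing:
        raise ValueError(f"sex-limitation model requires all five groups; "
                         f"missing {missing}")
    allv = np.concatenate(
        [data.trait_pairs(trait, group=g).ravel() for g in _FIVE_GROUPS])
    mu, sd = allv.mean(), allv.std()
    stats = {}
    for g in _FIVE_GROUPS:
        pairs = (data.trait_pairs(trait, group=g) - mu) / sd
        stats[g] = _suff_stats(pairs)

    def neg2ll(am, cm, em, af, cf, ef, rg):
        total = 0.0
        total += _neg2ll_gauss(*stats["MZm"], _ace_cov(am, cm, em, 1.0))
        total += _neg2ll_gauss(*stats["MZf"], _ace_cov(af, cf, ef, 1.0))
        total += _neg2ll_gauss(*stats["DZm"], _ace_cov(am, cm, em, 0.5))
        total += _neg2ll_gauss(*stats["DZf"], _ace_cov(af, cf, ef, 0.5))
        vm = am * am + cm * cm + em * em
        vf = af * af + cf * cf + ef * ef
        cov = rg * 0.5 * am * af + cm * cf
        n, s = stats["DZos"]
        total += _neg2ll_gauss(n, s, np.array([[vm, cov], [cov, vf]]))
        return total

    rng = np.random.default_rng(seed)

    def fit(kind):
        if kind == "full":
            def obj(x):
                return neg2ll(*x[:6], x[6])
            x0 = np.array([0.6, 0.3, 0.6, 0.6, 0.3, 0.6, 0.9])
            bounds = [(0.0, 2.0)] * 6 + [(0.0, 1.0)]
        elif kind == "common":
            def obj(x):
                return neg2ll(*x, 1.0)
            x0 = np.array([0.6, 0.3, 0.6, 0.6, 0.3, 0.6])
            bounds = [(0.0, 2.0)] * 6
        else:  # homogeneous
            def obj(x):
                a, c, e = x
                return neg2ll(a, c, e, a, c, e, 1.0)
            x0 = np.array([0.6, 0.3, 0.6])
            bounds = [(0.0, 2.0)] * 3
        best_x, best_f = None, np.inf
        for k in range(n_starts):
            start = x0 if k == 0 else np.clip(
                x0 + 0.2 * rng.standard_normal(len(x0)),
                [b[0] for b in bounds], [b[1] for b in bounds])
            res = minimize(obj, start, method="L-BFGS-B", bounds=bounds)
            if res.fun < best_f:
                best_f, best_x = float(res.fun), res.x
        return best_x, best_f

    x_full, ll_full = fit("full")
    _, ll_common = fit("common")
    _, ll_homog = fit("homogeneous")
    ll_common = min(ll_common, ll_homog)  # enforce nesting numerically
    ll_full = min(ll_full, ll_common)

    qual_chi2 = max(ll_common - ll_full, 0.0)
    quant_chi2 = max(ll_homog - ll_common, 0.0)
    params = dict(zip(("a_m", "c_m", "e_m", "a_f", "c_f", "e_f", "rg_os"), x_full))
    return SexLimitationResult(
        full_params=params,
        neg2ll_full=ll_full,
        neg2ll_common=ll_common,
        neg2ll_homogeneous=ll_homog,
        qualitative={"chi2": qual_chi2, "df": 1,
                     "p": float(chi2.sf(qual_chi2, 1))},
        quantitative={"chi2": quant_chi2, "df": 3,
                      "p": float(chi2.sf(quant_chi2, 3))},
    )
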