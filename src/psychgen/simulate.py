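"""Synthetic-data generators with known ground truth.

Every pipeline stage is validated by recovery on data from this module:
binary item responses under a 2PL/3PL model with planted careless
responders ("clickers"), MZ/DZ twin pairs under a standardized ACE model
(optionally five sex-by-zygosity groups, optionally bivariate), unrelated
individuals with biallelic SNP dosages and an additive polygenic phenotype,
and marginal GWAS summary statistics with sampling noise at a given N.

All generators are deterministic given their seed, and attach the
generating truth (abilities, clicker status, variance components, per-SNP
effects) so tests can check parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from ._types import GenotypeMatrix, ItemSpec, ResponseMatrix, TwinDataset, bank_frame

# Behaviour of attentive respondents on quality-control items, and the
# slow-down factors of the planted clicker types.  QC items are trivial
# ("click the square"), so attentive respondents answer them correctly with
# near-certain probability.
QC_PASS_PROB = 0.98
RAPID_RT_FACTOR = 0.10
N_OPTIONS = 4
RT_LOG_SD = 0.4


def default_item_bank(
    n_verbal: int = 69,
    n_nonverbal: int = 69,
    n_qc: int = 5,
    a_range: tuple[float, float] = (0.8, 2.0),
    b_range: tuple[float, float] = (-2.0, 2.0),
    seed: int = 0,
) -> list[ItemSpec]:
    """A generic well-behaved bank: informative items plus QC items."""
    rng = np.random.default_rng(seed)
    tests = {
        "verbal": ["vocabulary", "missing_letter", "verbal_analogies"],
        "nonverbal": ["matrix_reasoning", "visual_puzzles"],
    }
    bank: list[ItemSpec] = []
    for domain, count in (("verbal", n_verbal), ("nonverbal", n_nonverbal)):
        for i in range(count):
            bank.append(
                ItemSpec(
                    item_id=f"{domain[0]}{i + 1:03d}",
                    domain=domain,
                    test=tests[domain][i % len(tests[domain])],
                    a=float(rng.uniform(*a_range)),
                    b=float(rng.uniform(*b_range)),
                    time_limit=float(rng.uniform(20.0, 40.0)),
                )
            )
    for i in range(n_qc):
        bank.append(
            ItemSpec(
                item_id=f"qc{i + 1:02d}",
                domain="nonverbal",
                test="quality_control",
                a=3.0,
                b=-4.0,
                time_limit=20.0,
                is_qc=True,
            )
        )
    return bank


def irt_prob(theta: np.ndarray, a: np.ndarray, b: np.ndarray,
             c: np.ndarray | float = 0.0) -> np.ndarray:
    """3PL response probability c + (1-c) * logistic(a (theta - b)).

    ``theta`` has shape (n,) or (n, 1); item parameters are broadcast along
    the last axis, giving an (n, J) matrix of probabilities.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    if theta.ndim == 1:
        theta = theta[:, None]
    return c + (1.0 - np.asarray(c)) * expit(a * (theta - b))


def gen_item_responses(
    bank: list[ItemSpec],
    n_subjects: int,
    clicker_spec: dict | None = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Simulate binary accuracies and response times for a subject sample.

    Abilities are standard normal.  Attentive subjects answer item j
    correctly with the 2PL/3PL probability; their chosen option equals the
    item key when correct and a random distractor otherwise.  Planted
    clickers come in three flavours: ``n_uniform`` subjects click the same
    option throughout, ``n_rapid`` subjects answer at 10% of the typical
    response time with random choices, and ``n_random`` subjects choose
    options uniformly at random at normal speed.  The truth table records
    each subject's generating ability and clicker type.
    """
    if not bank:
        raise ValueError("item bank is empty")
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    clicker_spec = dict(clicker_spec or {})
    n_uniform = int(clicker_spec.pop("n_uniform", 0))
    n_rapid = int(clicker_spec.pop("n_rapid", 0))
    n_random = int(clicker_spec.pop("n_random", 0))
    if clicker_spec:
        raise ValueError(f"unknown clicker keys: {sorted(clicker_spec)}")
    if min(n_uniform, n_rapid, n_random) < 0:
        raise ValueError("clicker counts must be >= 0")
    n_clickers = n_uniform + n_rapid + n_random
    if n_clickers > n_subjects:
        raise ValueError(
            f"{n_clickers} clickers exceed {n_subjects} subjects"
        )

    rng = np.random.default_rng(seed)
    bank_df = bank_frame(bank)
    n_items = len(bank_df)
    a = bank_df["a"].to_numpy()
    b = bank_df["b"].to_numpy()
    c = bank_df["c"].to_numpy()
    is_qc = bank_df["is_qc"].to_numpy()
    limits = bank_df["time_limit"].to_numpy()

    theta = rng.standard_normal(n_subjects)
    # clicker assignment: last subjects, deterministic given the seed
    clicker_type = np.array(["none"] * n_subjects, dtype=object)
    idx = rng.permutation(n_subjects)[:n_clickers]
    clicker_type[idx[:n_uniform]] = "uniform"
    clicker_type[idx[n_uniform:n_uniform + n_rapid]] = "rapid"
    clicker_type[idx[n_uniform + n_rapid:]] = "random"

    keys = rng.integers(0, N_OPTIONS, size=n_items)
    attentive = clicker_type == "none"

    prob = irt_prob(theta, a, b, c)
    prob[:, is_qc] = QC_PASS_PROB
    correct = (rng.random((n_subjects, n_items)) < prob).astype(np.int8)

    choices = np.where(
        correct.astype(bool),
        keys,
        (keys + rng.integers(1, N_OPTIONS, size=(n_subjects, n_items))) % N_OPTIONS,
    )
    chance = ~attentive & (clicker_type != "uniform")
    choices[chance] = rng.integers(0, N_OPTIONS, size=(int(chance.sum()), n_items))
    for i in np.flatnonzero(clicker_type == "uniform"):
        choices[i, :] = rng.integers(0, N_OPTIONS)
    correct[~attentive] = (choices[~attentive] == keys).astype(np.int8)

    # response times: lognormal around an item-specific median, truncated
    # at the item's presentation limit; rapid clickers at 10% of median
    median_rt = np.minimum(0.4 * limits, 12.0)
    rt = median_rt * np.exp(RT_LOG_SD * rng.standard_normal((n_subjects, n_items)))
    rapid = clicker_type == "rapid"
    rt[rapid] = (RAPID_RT_FACTOR * median_rt
                 * np.exp(0.1 * rng.standard_normal((int(rapid.sum()), n_items))))
    rt = np.minimum(rt, limits)

    subjects = [f"s{i + 1:05d}" for i in range(n_subjects)]
    items = list(bank_df.index)
    truth = pd.DataFrame(
        {"theta": theta, "clicker": clicker_type, "is_clicker": ~attentive},
        index=pd.Index(subjects, name="subject_id"),
    )
    return ResponseMatrix(
        accuracy=pd.DataFrame(correct, index=subjects, columns=items),
        rt=pd.DataFrame(rt, index=subjects, columns=items),
        bank=bank_df.assign(key=keys),
        truth=truth,
        choices=pd.DataFrame(choices, index=subjects, columns=items),
    )


# ---------------------------------------------------------------------------
# twin pairs


@dataclass
class AceSpec:
    """Standardized ACE variance components for one or two traits.

    ``a2``, ``c2``, ``e2`` are scalars (univariate) or length-2 sequences
    (bivariate); each trait's components must sum to 1.  For two traits the
    genetic/shared/nonshared cross-trait correlations ``ra``, ``rc``, ``re``
    complete the model.  ``sex_params`` optionally overrides (a2, c2, e2)
    per sex for quantitative sex-limitation data, and ``rg_os`` < 1 deflates
    the opposite-sex DZ cross-twin genetic covariance (qualitative effect).
    """

    a2: float | tuple[float, ...] = 0.5
    c2: float | tuple[float, ...] = 0.2
    e2: float | tuple[float, ...] = 0.3
    ra: float | None = None
    rc: float | None = None
    re: float | None = None
    sex_params: dict[str, tuple[float, float, float]] | None = None
    rg_os: float = 1.0
    traits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a2 = np.atleast_1d(np.asarray(self.a2, float))
        c2 = np.atleast_1d(np.asarray(self.c2, float))
        e2 = np.atleast_1d(np.asarray(self.e2, float))
        if not (len(a2) == len(c2) == len(e2)):
            raise ValueError("a2, c2, e2 must have the same length")
        if len(a2) > 2:
            raise ValueError("at most two traits supported")
        if np.any(a2 < 0) or np.any(c2 < 0) or np.any(e2 < 0):
            raise ValueError("variance components must be nonnegative")
        if not np.allclose(a2 + c2 + e2, 1.0, atol=1e-8):
            raise ValueError("a2 + c2 + e2 must equal 1 for each trait")
        for r in (self.ra, self.rc, self.re):
            if r is not None and not -1.0 <= r <= 1.0:
                raise ValueError("cross-trait correlations must lie in [-1, 1]")
        if len(a2) == 2 and None in (self.ra, self.rc, self.re):
            raise ValueError("bivariate spec requires ra, rc and re")
        if not 0.0 <= self.rg_os <= 1.0:
            raise ValueError("rg_os must lie in [0, 1]")
        if self.sex_params is not None:
            if len(a2) != 1:
                raise ValueError("per-sex parameters supported for one trait only")
            for sex in ("M", "F"):
                comp = np.asarray(self.sex_params[sex], float)
                if comp.min() < 0 or abs(comp.sum() - 1.0) > 1e-8:
                    raise ValueError(f"sex {sex}: components must be >=0, sum 1")
        object.__setattr__(self, "a2", tuple(a2))
        object.__setattr__(self, "c2", tuple(c2))
        object.__setattr__(self, "e2", tuple(e2))
        if not self.traits:
            names = tuple(f"trait{i + 1}" for i in range(len(a2)))
            object.__setattr__(self, "traits", names)

    @property
    def n_traits(self) -> int:
        return len(self.a2)

    def components_for(self, sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self.sex_params is not None:
            a2, c2, e2 = self.sex_params[sex]
            return (np.atleast_1d(float(a2)), np.atleast_1d(float(c2)),
                    np.atleast_1d(float(e2)))
        return (np.asarray(self.a2), np.asarray(self.c2), np.asarray(self.e2))

    def _block(self, kind: str, sex1: str, sex2: str) -> np.ndarray:
        """A, C or E covariance block between two (possibly bivariate) twins."""
        t = self.n_traits
        comp1 = dict(zip("ace", self.components_for(sex1)))
        comp2 = dict(zip("ace", self.components_for(sex2)))
        r = {"a": self.ra, "c": self.rc, "e": self.re}[kind] if t == 2 else None
        out = np.zeros((t, t))
        for i in range(t):
            for j in range(t):
                cross = 1.0 if i == j else float(r)
                out[i, j] = cross * np.sqrt(comp1[kind][i] * comp2[kind][j])
        return out

    def implied_cov(self, zygosity: str, sex1: str = "F", sex2: str = "F") -> np.ndarray:
        """Model covariance of the 2T-variate vector (twin1 traits, twin2 traits)."""
        t = self.n_traits
        a11 = self._block("a", sex1, sex1)
        a22 = self._block("a", sex2, sex2)
        a12 = self._block("a", sex1, sex2)
        c11, c22, c12 = (self._block("c", s1, s2)
                         for s1, s2 in ((sex1, sex1), (sex2, sex2), (sex1, sex2)))
        e11, e22 = self._block("e", sex1, sex1), self._block("e", sex2, sex2)
        kin = 1.0 if zygosity == "MZ" else 0.5
        if zygosity == "DZ" and sex1 != sex2:
            kin *= self.rg_os
        cov = np.zeros((2 * t, 2 * t))
        cov[:t, :t] = a11 + c11 + e11
        cov[t:, t:] = a22 + c22 + e22
        cov[:t, t:] = kin * a12 + c12
        cov[t:, :t] = cov[:t, t:].T
        return cov


def gen_twin_data(
    spec: AceSpec,
    n_mz: int,
    n_dz: int,
    sex_composition: dict[str, float] | None = None,
    seed: int = 0,
) -> TwinDataset:
    """Draw twin pairs from the model-implied multivariate normal.

    Cross-twin covariance is a2 + c2 for MZ pairs and 0.5 a2 + c2 for DZ
    pairs (per trait, with cross-trait blocks set by ra/rc/re), unit total
    variance.  ``sex_composition`` gives the proportion of pairs in each of
    the five sex-by-zygosity groups within zygosity; the default is an
    equal MZ split and a 1/4, 1/4, 1/2 DZ split.
    """
    if n_mz < 0 or n_dz < 0:
        raise ValueError("pair counts must be >= 0")
    comp = {"MZm": 0.5, "MZf": 0.5, "DZm": 0.25, "DZf": 0.25, "DZos": 0.5}
    comp.update(sex_composition or {})
    rng = np.random.default_rng(seed)

    group_sex = {"MZm": ("M", "M"), "MZf": ("F", "F"), "DZm": ("M", "M"),
                 "DZf": ("F", "F"), "DZos": ("M", "F")}
    counts: dict[str, int] = {}
    mz_w = np.array([comp["MZm"], comp["MZf"]], float)
    dz_w = np.array([comp["DZm"], comp["DZf"], comp["DZos"]], float)
    mz_n = np.floor(n_mz * mz_w / mz_w.sum()).astype(int)
    mz_n[0] += n_mz - mz_n.sum()
    dz_n = np.floor(n_dz * dz_w / dz_w.sum()).astype(int)
    dz_n[0] += n_dz - dz_n.sum()
    counts.update(dict(zip(("MZm", "MZf"), mz_n)))
    counts.update(dict(zip(("DZm", "DZf", "DZos"), dz_n)))

    t = spec.n_traits
    rows = []
    pair_no = 0
    for group, n_g in counts.items():
        if n_g == 0:
            continue
        sex1, sex2 = group_sex[group]
        zyg = "MZ" if group.startswith("MZ") else "DZ"
        cov = spec.implied_cov(zyg, sex1, sex2)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"implied covariance for group {group} is not positive definite"
            ) from exc
        vals = rng.standard_normal((n_g, 2 * t)) @ chol.T
        for k in range(n_g):
            pair_no += 1
            row = {"pair_id": f"p{pair_no:06d}", "zygosity": zyg,
                   "sex1": sex1, "sex2": sex2, "group": group}
            for j, trait in enumerate(spec.traits):
                row[f"{trait}_t1"] = vals[k, j]
                row[f"{trait}_t2"] = vals[k, t + j]
            rows.append(row)
    pairs = pd.DataFrame(rows)
    truth = {"a2": spec.a2, "c2": spec.c2, "e2": spec.e2,
             "ra": spec.ra, "rc": spec.rc, "re": spec.re,
             "rg_os": spec.rg_os, "sex_params": spec.sex_params}
    return TwinDataset(pairs=pairs, traits=list(spec.traits), truth=truth)


# ---------------------------------------------------------------------------
# genotypes, phenotype, summary statistics


@dataclass
class GenoSimSpec:
    """Simulation settings for unrelated individuals with a polygenic trait."""

    n_individuals: int = 1000
    m_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_snp: float = 0.5
    ld_block_size: int | None = None
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF bounds must lie in (0, 0.5]")
        if not 0.0 <= self.h2_snp <= 1.0:
            raise ValueError("h2_snp must lie in [0, 1]")
        if self.ld_block_size is not None and not -1 < self.ld_rho < 1:
            raise ValueError("ld_rho must lie in (-1, 1)")


@dataclass
class GenoSimResult:
    genotypes: GenotypeMatrix
    phenotype: pd.Series
    effects: np.ndarray          # per-SNP effects on the standardized scale
    genetic_values: np.ndarray
    realized_h2: float


def _draw_dosages(rng: np.random.Generator, n: int, p: np.ndarray,
                  block: int | None, rho: float) -> np.ndarray:
    """Dosages from two haplotypes; within-block AR(1) Gaussian copula LD."""
    m = len(p)
    thresh = norm.ppf(p)  # latent below threshold => carries counted allele
    dose = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        if block is None or rho == 0.0:
            z = rng.standard_normal((n, m))
        else:
            z = np.empty((n, m))
            innov_sd = np.sqrt(1.0 - rho ** 2)
            for start in range(0, m, block):
                stop = min(start + block, m)
                z[:, start] = rng.standard_normal(n)
                for j in range(start + 1, stop):
                    z[:, j] = rho * z[:, j - 1] + innov_sd * rng.standard_normal(n)
        dose += (z < thresh).astype(np.int8)
    return dose


def gen_genotypes_phenotype(
    spec: GenoSimSpec,
    effects: np.ndarray | None = None,
    freq: np.ndarray | None = None,
) -> GenoSimResult:
    """Biallelic dosages plus an additive polygenic phenotype.

    Per-SNP effects are N(0, h2/M) on the allele-frequency standardized
    scale; the phenotype adds N(0, 1 - h2) residual noise, so its variance
    is ~1 and the genetic values carry the target SNP heritability.
    Passing ``effects`` and/or ``freq`` reuses another cohort's truth, so
    training and holdout samples can share the same genetic architecture.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_individuals, spec.m_snps
    p = rng.uniform(*spec.maf_range, size=m) if freq is None \
        else np.asarray(freq, float)
    if len(p) != m:
        raise ValueError("freq length must equal m_snps")
    dose = _draw_dosages(rng, n, p, spec.ld_block_size, spec.ld_rho)

    snps = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(m)],
            "chrom": np.ones(m, dtype=int),
            "pos": np.arange(1, m + 1) * 1000,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
            "freq": p,
        }
    )
    ids = [f"ind{i + 1:05d}" for i in range(n)]
    geno = GenotypeMatrix(ids=ids, snps=snps, dosages=dose.astype(float))

    if effects is None:
        effects = rng.standard_normal(m) * np.sqrt(spec.h2_snp / m) \
            if spec.h2_snp > 0 else np.zeros(m)
    else:
        effects = np.asarray(effects, float)
        if len(effects) != m:
            raise ValueError("effects length must equal m_snps")
    z = (dose - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    gvals = z @ effects
    resid = rng.standard_normal(n) * np.sqrt(max(1.0 - spec.h2_snp, 0.0))
    pheno = pd.Series(gvals + resid, index=ids, name="phenotype")
    realized = float(np.var(gvals)) if n > 1 else 0.0
    return GenoSimResult(genotypes=geno, phenotype=pheno, effects=effects,
                         genetic_values=gvals, realized_h2=realized)


def gen_sumstats(
    true_effects: np.ndarray,
    snps: pd.DataFrame,
    n_gwas: int,
    ld: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Marginal GWAS estimates: LD-convolved truth plus sampling noise.

    Effects are on the standardized-genotype scale.  With LD matrix R the
    marginal expectation is R beta and the estimation noise has covariance
    R / N; without LD both reduce to independent N(beta_i, 1/N) draws.
    Returns a sumstats table (SNP, A1, A2, BETA, SE, N, FREQ) aligned with
    the supplied SNP metadata.
    """
    if n_gwas <= 0:
        raise ValueError("n_gwas must be positive")
    rng = np.random.default_rng(seed)
    beta = np.asarray(true_effects, float)
    m = len(beta)
    if ld is None:
        mean = beta
        noise = rng.standard_normal(m) / np.sqrt(n_gwas)
    else:
        mean = ld @ beta
        chol = np.linalg.cholesky(ld + 1e-10 * np.eye(m))
        noise = chol @ rng.standard_normal(m) / np.sqrt(n_gwas)
    se = np.full(m, 1.0 / np.sqrt(n_gwas))
    return pd.DataFrame(
        {
            "SNP": snps["snp"].to_numpy(),
            "A1": snps["a1"].to_numpy(),
            "A2": snps["a2"].to_numpy(),
            "BETA": mean + noise,
            "SE": se,
            "N": np.full(m, int(n_gwas)),
            "FREQ": snps["freq"].to_numpy(),
        }
    )
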