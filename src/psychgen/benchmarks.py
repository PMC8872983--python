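"""Reference simulation studies at the design sizes of the original twin
cohort: each function regenerates its inputs from scratch with known
ground truth, runs the corresponding estimator, and returns the recovered
quantity (averaged over seeded replicates).

These studies pin the estimators to the published design: 639 MZ and 777
DZ twin pairs, 1,365 genotyped unrelated individuals, a 138-item bank
calibrated on 144 subjects, and a five-test battery at n = 4,545.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._types import ItemSpec
from .irt import ReductionConfig, fit_irt, reduce_items
from .pgs import compute_grm, greml, ldpred_inf, polygenic_score, score_and_r2
from .psych import pca_with_parallel
from .simulate import (
    AceSpec,
    GenoSimSpec,
    gen_genotypes_phenotype,
    gen_item_responses,
    gen_twin_data,
)
from .twin import falconer, fit_ace

__all__ = [
    "twin_a2_recovery",
    "greml_h2_recovery",
    "pgs_delta_r2",
    "flat_item_bank",
    "structured_item_bank",
    "stage1_flat_count",
    "final_battery_size",
    "pc1_proportion",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def twin_a2_recovery(
    r_mz: float,
    r_dz: float,
    n_mz: int = 639,
    n_dz: int = 777,
    n_reps: int = 20,
    seed: int = 0,
) -> dict:
    """Mean ML estimate of the standardized A component on twin samples
    drawn at the given intraclass correlations."""
    truth = falconer(r_mz, r_dz)
    spec = AceSpec(a2=truth["a2"], c2=truth["c2"], e2=truth["e2"])
    estimates = []
    for s in _child_seeds(seed, n_reps):
        data = gen_twin_data(spec, n_mz, n_dz, seed=int(s))
        fit = fit_ace(data, ci_method="none", seed=int(s))
        estimates.append(fit.a2)
    return {"mean_a2": float(np.mean(estimates)),
            "sd_a2": float(np.std(estimates)),
            "true_a2": truth["a2"],
            "n_pairs": n_mz + n_dz,
            "n_reps": n_reps}


def greml_h2_recovery(
    n: int = 1365,
    m: int = 5000,
    h2: float = 0.37,
    n_reps: int = 20,
    seed: int = 0,
) -> dict:
    """Mean AI-REML SNP-heritability estimate on unrelated individuals."""
    estimates = []
    for s in _child_seeds(seed, n_reps):
        sim = gen_genotypes_phenotype(
            GenoSimSpec(n_individuals=n, m_snps=m, maf_range=(0.05, 0.5),
                        h2_snp=h2, seed=int(s)))
        grm = compute_grm(sim.genotypes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = greml(sim.phenotype, grm)
        estimates.append(res.h2)
    return {"mean_h2": float(np.mean(estimates)),
            "sd_h2": float(np.std(estimates)),
            "true_h2": h2, "n": n, "m": m, "n_reps": n_reps}


def pgs_delta_r2(
    n_train: int = 2591,
    n_holdout: int = 1365,
    m: int = 2000,
    h2: float = 0.37,
    n_reps: int = 20,
    seed: int = 0,
) -> dict:
    """Mean incremental R^2 of an infinitesimal-prior polygenic score.

    A training cohort provides marginal GWAS estimates; weights are
    shrunken with the holdout panel as the LD reference and evaluated in
    the non-overlapping holdout.  The expected value under the
    infinitesimal model is h^4 N / (h^2 N + M).
    """
    deltas = []
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(int(s))
        train = gen_genotypes_phenotype(
            GenoSimSpec(n_individuals=n_train, m_snps=m, h2_snp=h2,
                        seed=int(rng.integers(2 ** 31))))
        z = train.genotypes.standardized()
        y = train.phenotype.to_numpy()
        y = (y - y.mean()) / y.std()
        beta_hat = z.T @ y / len(y)
        ss = pd.DataFrame({
            "SNP": train.genotypes.snps["snp"],
            "A1": train.genotypes.snps["a1"],
            "A2": train.genotypes.snps["a2"],
            "BETA": beta_hat,
            "SE": 1.0 / np.sqrt(n_train),
            "N": n_train,
            "FREQ": train.genotypes.snps["freq"],
        })
        holdout = gen_genotypes_phenotype(
            GenoSimSpec(n_individuals=n_holdout, m_snps=m, h2_snp=h2,
                        seed=int(rng.integers(2 ** 31))),
            effects=train.effects,
            freq=train.genotypes.snps["freq"].to_numpy(),
        )
        weights = ldpred_inf(ss, holdout.genotypes, h2=h2, n_gwas=n_train)
        score = polygenic_score(holdout.genotypes, weights)
        res = score_and_r2(holdout.phenotype, score)
        deltas.append(float(res["delta_r2"].iloc[0]))
    expected = h2 ** 2 * n_train / (h2 * n_train + m)
    return {"mean_delta_r2": float(np.mean(deltas)),
            "sd_delta_r2": float(np.std(deltas)),
            "expected_delta_r2": expected,
            "n_train": n_train, "n_holdout": n_holdout, "m": m,
            "n_reps": n_reps}


def flat_item_bank(n_flat: int = 37, n_total: int = 138,
                   seed: int = 0) -> list[ItemSpec]:
    """A bank with planted zero-discrimination items among informative ones."""
    rng = np.random.default_rng(seed)
    bank = []
    for j in range(n_flat):
        bank.append(ItemSpec(f"flat{j:03d}",
                             "verbal" if j % 2 else "nonverbal", "mixed",
                             a=0.0, b=0.0))
    for j in range(n_total - n_flat):
        bank.append(ItemSpec(f"good{j:03d}",
                             "verbal" if j % 2 else "nonverbal", "mixed",
                             a=float(rng.uniform(0.8, 2.0)),
                             b=float(rng.uniform(-2.0, 2.0))))
    return bank


def structured_item_bank(seed: int = 0) -> list[ItemSpec]:
    """The full planted reduction scenario: 37 flat items, 51 low-information
    or out-of-range items, 20 informative verbal + 10 verbal duplicates,
    and 20 informative nonverbal items (138 total)."""
    rng = np.random.default_rng(seed)
    bank = []
    for j in range(37):
        bank.append(ItemSpec(f"flat{j:03d}",
                             "verbal" if j % 2 else "nonverbal", "mixed",
                             a=0.0, b=0.0))
    for j in range(51):
        if j % 3 == 2:
            # informative slope but difficulty far outside the target range
            bank.append(ItemSpec(
                f"low{j:03d}", "verbal" if j % 2 else "nonverbal", "mixed",
                a=float(rng.uniform(1.0, 1.5)),
                b=float(rng.choice([-1.0, 1.0]) * rng.uniform(3.6, 4.5))))
        else:
            bank.append(ItemSpec(
                f"low{j:03d}", "verbal" if j % 2 else "nonverbal", "mixed",
                a=float(rng.uniform(0.25, 0.5)),
                b=float(rng.uniform(-2.0, 2.0))))
    good_v = [ItemSpec(f"goodv{j:02d}", "verbal", "mixed",
                       a=float(rng.uniform(1.3, 2.0)),
                       b=float(-2.0 + 4.0 * j / 19)) for j in range(20)]
    dup_v = [ItemSpec(f"dupv{j:02d}", "verbal", "mixed",
                      a=good_v[j].a, b=good_v[j].b) for j in range(10)]
    good_n = [ItemSpec(f"goodn{j:02d}", "nonverbal", "mixed",
                       a=float(rng.uniform(1.3, 2.0)),
                       b=float(-2.0 + 4.0 * j / 19)) for j in range(20)]
    return bank + good_v + dup_v + good_n


def stage1_flat_count(
    n_subjects: int = 144,
    n_flat: int = 37,
    n_total: int = 138,
    n_seeds: int = 10,
    seed: int = 0,
) -> dict:
    """Number of items removed by stage 1, majority-voted over seeds.

    The calibration sample is deliberately small, so each run is noisy;
    an item counts as removed when stage 1 drops it in more than half of
    the seeded runs.
    """
    removed_runs = []
    for s in _child_seeds(seed, n_seeds):
        bank = flat_item_bank(n_flat, n_total, seed=int(s))
        resp = gen_item_responses(bank, n_subjects, seed=int(s))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_irt(resp.accuracy, "2PL")
        report = reduce_items(fit, resp.bank["domain"],
                              ReductionConfig(stage3_domains=()))
        removed_runs.append(report["stage"] == "stage1_flat")
    votes = pd.concat(
        [r.rename(i) for i, r in enumerate(removed_runs)], axis=1)
    majority = (votes.mean(axis=1) > 0.5).sum()
    return {"stage1_removed": int(majority),
            "per_seed": [int(r.sum()) for r in removed_runs],
            "n_planted": n_flat, "n_seeds": n_seeds}


def final_battery_size(n_subjects: int = 2000, seed: int = 0) -> dict:
    """Size of the battery surviving the full three-stage reduction on the
    structured planted bank."""
    bank = structured_item_bank(seed=seed)
    resp = gen_item_responses(bank, n_subjects, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_irt(resp.accuracy, "2PL")
    report = reduce_items(fit, resp.bank["domain"], ReductionConfig())
    kept = report[report["stage"] == "kept"]
    return {"battery_size": int(len(kept)),
            "per_domain": kept["domain"].value_counts().to_dict(),
            "stage_counts": report["stage"].value_counts().to_dict()}


def pc1_proportion(
    n: int = 4545,
    k: int = 5,
    rho: float = 0.40,
    n_reps: int = 20,
    seed: int = 0,
) -> dict:
    """Mean proportion of variance on the first principal component of k
    equicorrelated test scores; closed form (1 + (k-1) rho) / k."""
    props = []
    chol = np.linalg.cholesky(rho * np.ones((k, k)) + (1 - rho) * np.eye(k))
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(int(s))
        data = pd.DataFrame(rng.standard_normal((n, k)) @ chol.T,
                            columns=[f"t{i + 1}" for i in range(k)])
        out = pca_with_parallel(data, n_reps=50, seed=int(s))
        props.append(float(out["proportions"][0]))
    return {"mean_pc1_proportion": float(np.mean(props)),
            "expected": (1 + (k - 1) * rho) / k,
            "n": n, "n_reps": n_reps}
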