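"""End-to-end pipeline driver.

A YAML config names an output directory, a master seed and an ordered
stage list; each stage reads what earlier stages produced (in memory and
on disk), runs the corresponding library function, and appends its
numbers to a machine-readable results dictionary.  The ``report`` stage
writes ``results.json`` and a human-readable ``report.md``.  Stage
failures abort with the stage name attached; every stochastic stage
records the seed it used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, irt, pgs, psych, twin
from .simulate import (
    AceSpec,
    GenoSimSpec,
    default_item_bank,
    gen_genotypes_phenotype,
    gen_item_responses,
    gen_sumstats,
    gen_twin_data,
)

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "irt", "reduce", "qc", "psych", "twin",
                "grm", "greml", "pgs", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int
    stages: list[str]
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        stages = raw.get("stages", [])
        unknown = [s for s in stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {KNOWN_STAGES}")
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        return cls(
            out_dir=Path(raw.get("out_dir", "pipeline_out")),
            seed=int(raw["seed"]),
            stages=stages,
            params={k: v for k, v in raw.items()
                    if k not in ("out_dir", "seed", "stages")},
        )

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}) or {})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the results dict."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    ctx: dict = {"results": {"seed": config.seed}}
    for stage in config.stages:
        fn = _STAGES[stage]
        logger.info("running stage %s", stage)
        try:
            fn(config, ctx)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(stage, exc) from exc
    return ctx["results"]


def _require(ctx: dict, key: str, stage: str, needed_by: str) -> object:
    if key not in ctx:
        raise ValueError(
            f"stage {needed_by!r} requires output of stage {stage!r}")
    return ctx[key]


def _stage_simulate(cfg: PipelineConfig, ctx: dict) -> None:
    p = cfg.stage_params("simulate")
    seed = int(p.get("seed", cfg.seed))
    rng = np.random.default_rng(seed)
    out = cfg.out_dir

    bank = default_item_bank(seed=int(rng.integers(2 ** 31)))
    resp = gen_item_responses(
        bank,
        n_subjects=int(p.get("n_subjects", 1000)),
        clicker_spec=p.get("clickers", {"n_uniform": 10, "n_rapid": 10,
                                        "n_random": 10}),
        seed=int(rng.integers(2 ** 31)),
    )
    io.write_responses(resp, out / "responses")
    ctx["responses"] = resp

    tw = p.get("twin", {})
    spec = AceSpec(a2=tw.get("a2", 0.57), c2=tw.get("c2", 0.08),
                   e2=tw.get("e2", 1.0 - tw.get("a2", 0.57) - tw.get("c2", 0.08)))
    twins = gen_twin_data(spec, n_mz=int(tw.get("n_mz", 639)),
                          n_dz=int(tw.get("n_dz", 777)),
                          seed=int(rng.integers(2 ** 31)))
    io.write_twin_csv(twins, out / "twins.csv")
    ctx["twins"] = twins

    g = p.get("geno", {})
    gspec = GenoSimSpec(
        n_individuals=int(g.get("n_individuals", 500)),
        m_snps=int(g.get("m_snps", 1000)),
        h2_snp=float(g.get("h2_snp", 0.37)),
        seed=int(rng.integers(2 ** 31)),
    )
    sim = gen_genotypes_phenotype(gspec)
    io.write_traw(sim.genotypes, out / "genotypes.traw")
    sim.phenotype.rename_axis("id").to_csv(out / "phenotype.csv")
    ss = gen_sumstats(sim.effects, sim.genotypes.snps,
                      n_gwas=int(g.get("n_gwas", 2000)),
                      seed=int(rng.integers(2 ** 31)))
    io.write_sumstats(ss, out / "sumstats.tsv")
    ctx["geno_sim"] = sim
    ctx["sumstats"] = ss

    io.write_sidecar(out / "simulate.yaml", seed=seed, params=p)
    ctx["results"]["simulate"] = {
        "seed": seed,
        "n_subjects": int(resp.accuracy.shape[0]),
        "n_items": int(resp.accuracy.shape[1]),
        "n_twin_pairs": int(len(twins.pairs)),
        "n_individuals": gspec.n_individuals,
        "m_snps": gspec.m_snps,
    }


def _stage_qc(cfg: PipelineConfig, ctx: dict) -> None:
    resp = _require(ctx, "responses", "simulate", "qc")
    p = cfg.stage_params("qc")
    config = psych.ClickerConfig(**p) if p else None
    flags = psych.detect_clickers(resp, config)
    flags.to_csv(cfg.out_dir / "clicker_flags.csv")
    keep = flags.index[~flags["is_clicker"]]
    ctx["clean_subjects"] = keep
    ctx["results"]["qc"] = {
        "n_flagged": int(flags["is_clicker"].sum()),
        "n_retained": int(len(keep)),
        "reasons": {col: int(flags[col].sum())
                    for col in ("qc_fail", "rapid", "uniform", "low_score")},
    }


def _stage_irt(cfg: PipelineConfig, ctx: dict) -> None:
    resp = _require(ctx, "responses", "simulate", "irt")
    p = cfg.stage_params("irt")
    subjects = ctx.get("clean_subjects", resp.accuracy.index)
    acc = resp.accuracy.loc[subjects, resp.scored_items]
    fit = irt.fit_irt(acc, model=p.get("model", "2PL"),
                      n_quadrature=int(p.get("n_quadrature", 61)),
                      tol=float(p.get("tol", 1e-5)),
                      max_iter=int(p.get("max_iter", 2000)))
    params = fit.params.join(resp.bank[["domain", "test"]])
    params.to_csv(cfg.out_dir / "item_parameters.csv")
    ctx["irt_fit"] = fit
    ctx["results"]["irt"] = {
        "model": fit.model,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "bic": fit.bic,
        "adjusted_bic": fit.adjusted_bic,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "n_dropped_items": len(fit.dropped_items),
    }


def _stage_reduce(cfg: PipelineConfig, ctx: dict) -> None:
    fit = _require(ctx, "irt_fit", "irt", "reduce")
    resp = _require(ctx, "responses", "simulate", "reduce")
    p = cfg.stage_params("reduce")
    rc = irt.ReductionConfig(**{k: v for k, v in p.items()})
    report = irt.reduce_items(fit, resp.bank["domain"], rc)
    report.to_csv(cfg.out_dir / "selection_report.csv")
    ctx["selection"] = report
    counts = report["stage"].value_counts().to_dict()
    kept = report[report["stage"] == "kept"]
    ctx["results"]["reduce"] = {
        "stage_counts": {k: int(v) for k, v in counts.items()},
        "final_battery": int(len(kept)),
        "final_per_domain": {d: int(c) for d, c in
                             kept["domain"].value_counts().items()},
    }


def _stage_psych(cfg: PipelineConfig, ctx: dict) -> None:
    resp = _require(ctx, "responses", "simulate", "psych")
    subjects = ctx.get("clean_subjects", resp.accuracy.index)
    kept_items = resp.scored_items
    if "selection" in ctx:
        sel = ctx["selection"]
        kept_items = [it for it in sel.index[sel["stage"] == "kept"]]
    acc = resp.accuracy.loc[subjects, kept_items]
    domains = resp.bank.loc[kept_items, "domain"]
    tests = resp.bank.loc[kept_items, "test"]
    test_scores = pd.DataFrame({
        t: acc[[it for it in kept_items if tests[it] == t]].sum(axis=1)
        for t in tests.unique()
    })
    pca = psych.pca_with_parallel(test_scores, seed=cfg.seed)
    rel = psych.reliability(acc)
    cfa = psych.one_factor_cfa(test_scores)
    comp = psych.composite(acc, scheme="sum_items")
    comp.to_csv(cfg.out_dir / "composites.csv")
    ctx["results"]["psych"] = {
        "pc1_proportion": float(pca["proportions"][0]),
        "n_retained_components": pca["n_retained"],
        "alpha": rel["alpha"],
        "omega_h": rel["omega_h"],
        "cfa": {k: float(cfa[k]) for k in ("cfi", "tli", "srmr")},
        "n_verbal_items": int((domains == "verbal").sum()),
        "n_nonverbal_items": int((domains == "nonverbal").sum()),
    }


def _stage_twin(cfg: PipelineConfig, ctx: dict) -> None:
    twins = _require(ctx, "twins", "simulate", "twin")
    p = cfg.stage_params("twin")
    corr = twin.twin_correlations(twins, n_boot=int(p.get("n_boot", 200)),
                                  seed=cfg.seed)
    corr.to_csv(cfg.out_dir / "twin_correlations.csv")
    r_mz = float(corr.loc["MZ", "r"])
    r_dz = float(corr.loc["DZ", "r"])
    falc = twin.falconer(r_mz, r_dz)
    fit = twin.fit_ace(twins, ci_method=p.get("ci_method", "profile"),
                       seed=cfg.seed)
    ctx["results"]["twin"] = {
        "r_mz": r_mz,
        "r_dz": r_dz,
        "falconer": {k: falc[k] for k in ("a2", "c2", "e2")},
        "ace": {"a2": fit.a2, "c2": fit.c2, "e2": fit.e2,
                "ci": fit.ci, "neg2ll": fit.neg2ll,
                "chi2_vs_saturated": fit.chi2_vs_saturated,
                "p_vs_saturated": fit.p_vs_saturated},
        "submodels": fit.submodels,
    }


def _stage_grm(cfg: PipelineConfig, ctx: dict) -> None:
    sim = _require(ctx, "geno_sim", "simulate", "grm")
    grm = pgs.compute_grm(sim.genotypes)
    io.write_grm(grm, cfg.out_dir / "grm")
    ctx["grm"] = grm
    p = cfg.stage_params("grm")
    retained = pgs.prune_related(grm, threshold=float(p.get("threshold", 0.05)))
    ctx["retained_ids"] = retained
    ctx["results"]["grm"] = {
        "n": grm.n,
        "n_after_pruning": len(retained),
        "mean_diagonal": float(np.mean(np.diag(grm.matrix))),
    }


def _stage_greml(cfg: PipelineConfig, ctx: dict) -> None:
    sim = _require(ctx, "geno_sim", "simulate", "greml")
    grm = _require(ctx, "grm", "grm", "greml")
    retained = ctx.get("retained_ids", grm.ids)
    idx = [grm.ids.index(i) for i in retained]
    sub = pgs.Grm(ids=list(retained),
                  matrix=grm.matrix[np.ix_(idx, idx)],
                  n_snps=grm.n_snps[np.ix_(idx, idx)])
    res = pgs.greml(sim.phenotype.loc[retained], sub)
    ctx["results"]["greml"] = {
        "sigma2_g": res.sigma2_g, "sigma2_e": res.sigma2_e,
        "h2": res.h2, "se_h2": res.se_h2, "n_used": res.n_used,
        "converged": res.converged,
    }


def _stage_pgs(cfg: PipelineConfig, ctx: dict) -> None:
    sim = _require(ctx, "geno_sim", "simulate", "pgs")
    ss = _require(ctx, "sumstats", "simulate", "pgs")
    p = cfg.stage_params("pgs")
    h2 = float(p.get("h2", 0.37))
    weights = pgs.ldpred_inf(ss, sim.genotypes, h2=h2,
                             window=int(p.get("window", 100)))
    score = pgs.polygenic_score(sim.genotypes, weights)
    score.rename_axis("id").to_csv(cfg.out_dir / "gps.csv")
    res = pgs.score_and_r2(sim.phenotype, score)
    ctx["results"]["pgs"] = {
        "delta_r2": float(res.loc["gps", "delta_r2"]),
        "beta": float(res.loc["gps", "beta"]),
        "se": float(res.loc["gps", "se"]),
        "t": float(res.loc["gps", "t"]),
    }


def _stage_report(cfg: PipelineConfig, ctx: dict) -> None:
    results = ctx["results"]
    with (cfg.out_dir / "results.json").open("w") as fh:
        json.dump(results, fh, indent=2, default=_json_default)
    lines = ["# Pipeline report", ""]
    for section, content in results.items():
        lines.append(f"## {section}")
        lines.append("```json")
        lines.append(json.dumps(content, indent=2, default=_json_default))
        lines.append("```")
        lines.append("")
    (cfg.out_dir / "report.md").write_text("\n".join(lines))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series, pd.Index)):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "irt": _stage_irt,
    "reduce": _stage_reduce,
    "psych": _stage_psych,
    "twin": _stage_twin,
    "grm": _stage_grm,
    "greml": _stage_greml,
    "pgs": _stage_pgs,
    "report": _stage_report,
}
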