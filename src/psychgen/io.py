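"""Interchange formats.

Genotypes are read from VCF 4.x (GT field, biallelic sites, via cyvcf2)
or PLINK ``.traw`` text dosages; the counted allele is the VCF alternate
allele.  Missing genotypes are imputed to twice the sample allele
frequency and flagged.  The GRM writer/reader uses the GCTA text format:
``<prefix>.grm`` holding (row, col, n_snps, value) lower-triangle triples
and ``<prefix>.grm.id`` holding family/individual ids.  GWAS summary
statistics are harmonized to a target genotype panel: allele swaps negate
the effect, strand-ambiguous palindromic SNPs with near-0.5 frequency are
dropped with a warning, odds ratios are converted to log-odds.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._types import GenotypeMatrix, ResponseMatrix, TwinDataset
from .pgs import Grm

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_vcf",
    "write_traw",
    "write_grm",
    "read_grm",
    "read_sumstats",
    "write_sumstats",
    "write_responses",
    "write_twin_csv",
    "read_twin_csv",
    "write_sidecar",
]


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read a dosage matrix from VCF (GT) or PLINK .traw text.

    Multi-allelic VCF records are an error.  Missing dosages are imputed
    to twice the allele frequency of the remaining samples and flagged in
    the ``missing`` mask.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "traw":
        return _read_traw(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    if not ids:
        raise ValueError(f"{path}: VCF has no samples")
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic site at {var.CHROM}:{var.POS} "
                f"(ALT={var.ALT})"
            )
        gts = np.array([[g[0], g[1]] for g in var.genotypes], dtype=float)
        gts[gts < 0] = np.nan
        dose = gts.sum(axis=1)  # count of ALT alleles
        rows.append(dose)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                     var.ALT[0], var.REF))
    if not rows:
        raise ValueError(f"{path}: no variant records")
    dose = np.array(rows).T  # individuals x SNPs
    return _finalize_dosages(ids, meta, dose)


def _read_traw(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    required = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    if list(df.columns[:6]) != required:
        raise ValueError(f"{path}: not a .traw header (got {list(df.columns[:6])})")
    if df.empty:
        raise ValueError(f"{path}: no variant records")
    samples = list(df.columns[6:])
    dose = df[samples].to_numpy(float).T
    meta = list(zip(df["SNP"], df["CHR"], df["POS"], df["COUNTED"], df["ALT"]))
    return _finalize_dosages(samples, meta, dose)


def _finalize_dosages(ids, meta, dose) -> GenotypeMatrix:
    missing = np.isnan(dose)
    freq = np.nanmean(dose, axis=0) / 2.0
    if missing.any():
        fill = np.broadcast_to(2.0 * freq, dose.shape)
        dose = np.where(missing, fill, dose)
    snps = pd.DataFrame(meta, columns=["snp", "chrom", "pos", "a1", "a2"])
    snps["pos"] = snps["pos"].astype(int)
    snps["freq"] = freq
    return GenotypeMatrix(ids=list(ids), snps=snps, dosages=dose,
                          missing=missing)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write integer dosages as a minimal VCF 4.2 with GT fields.

    The counted allele is written as ALT, so read_genotypes(write_vcf(x))
    reproduces the dosage matrix for integral dosages.
    """
    path = Path(path)
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.ids) + "\n")
        miss = genotypes.missing
        for j, row in genotypes.snps.iterrows():
            cells = []
            for i in range(genotypes.n):
                if miss is not None and miss[i, j]:
                    cells.append("./.")
                else:
                    cells.append(gt_codes[int(round(genotypes.dosages[i, j]))])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp']}\t{row['a2']}\t"
                     f"{row['a1']}\t.\t.\t.\tGT\t" + "\t".join(cells) + "\n")


def write_traw(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as PLINK .traw text (counted-allele dosages)."""
    path = Path(path)
    df = pd.DataFrame({
        "CHR": genotypes.snps["chrom"],
        "SNP": genotypes.snps["snp"],
        "(C)M": 0,
        "POS": genotypes.snps["pos"],
        "COUNTED": genotypes.snps["a1"],
        "ALT": genotypes.snps["a2"],
    })
    dose = genotypes.dosages.T.copy()
    if genotypes.missing is not None:
        dose[genotypes.missing.T] = np.nan
    samples = pd.DataFrame(dose, columns=genotypes.ids)
    pd.concat([df, samples], axis=1).to_csv(path, sep="\t", index=False,
                                            na_rep="NA")


# ---------------------------------------------------------------------------
# GRM text format


def write_grm(grm: Grm, prefix: str | Path) -> None:
    """GCTA-style text GRM: lower-triangle triples plus an id file."""
    prefix = Path(prefix)
    with open(f"{prefix}.grm", "w") as fh:
        for j in range(grm.n):
            for k in range(j + 1):
                fh.write(f"{j + 1}\t{k + 1}\t{int(grm.n_snps[j, k])}\t"
                         f"{grm.matrix[j, k]:.6f}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix: str | Path) -> Grm:
    """Read a GCTA-style text GRM; an absent triple is an error."""
    prefix = Path(prefix)
    ids = [line.split()[1] for line in
           Path(f"{prefix}.grm.id").read_text().splitlines() if line.strip()]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in GRM id file")
    n = len(ids)
    matrix = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=np.int64)
    for line in Path(f"{prefix}.grm").read_text().splitlines():
        if not line.strip():
            continue
        j_s, k_s, m_s, v_s = line.split()
        j, k = int(j_s) - 1, int(k_s) - 1
        if not (0 <= k <= j < n):
            raise ValueError(f"GRM triple ({j + 1},{k + 1}) outside id range")
        matrix[j, k] = matrix[k, j] = float(v_s)
        counts[j, k] = counts[k, j] = int(m_s)
    if np.isnan(matrix).any():
        j, k = np.argwhere(np.isnan(np.tril(matrix) )
                           & np.tril(np.ones((n, n), bool)))[0]
        raise ValueError(f"GRM file incomplete: missing triple ({j + 1},{k + 1})")
    if (counts <= 0).any():
        raise ValueError("GRM triples must have n_snps_used > 0")
    return Grm(ids=ids, matrix=matrix, n_snps=counts)


# ---------------------------------------------------------------------------
# summary statistics


PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def read_sumstats(
    path: str | Path,
    genotypes: GenotypeMatrix | None = None,
    palindrome_window: float = 0.08,
) -> pd.DataFrame:
    """Read a sumstats TSV and (optionally) harmonize to a genotype panel.

    Requires columns SNP, A1, A2, SE, N, FREQ and either BETA or OR (the
    latter converted to log-odds).  With a target panel: SNPs absent from
    the panel are dropped (count logged); records whose A1/A2 are swapped
    relative to the panel get BETA negated and FREQ flipped; palindromic
    SNPs with frequency within ``palindrome_window`` of 0.5 are dropped
    with a warning because their strand cannot be resolved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "BETA" not in df.columns:
        if "OR" not in df.columns:
            raise ValueError(f"{path}: needs a BETA or OR column")
        df["BETA"] = np.log(df["OR"].astype(float))
    for col in ("SNP", "A1", "A2", "SE", "N", "FREQ"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} absent")
    df = df[["SNP", "A1", "A2", "BETA", "SE", "N", "FREQ"]].copy()

    if genotypes is None:
        return df

    panel = genotypes.snps.set_index("snp")
    in_panel = df["SNP"].isin(panel.index)
    n_dropped = int((~in_panel).sum())
    if n_dropped:
        logger.info("read_sumstats: dropped %d SNPs absent from the target "
                    "panel", n_dropped)
    df = df[in_panel].copy()

    pal = df.apply(lambda r: (str(r["A1"]).upper(), str(r["A2"]).upper())
                   in PALINDROMIC, axis=1)
    ambiguous = pal & (np.abs(df["FREQ"].astype(float) - 0.5)
                       < palindrome_window)
    if ambiguous.any():
        warnings.warn(
            f"dropping {int(ambiguous.sum())} strand-ambiguous palindromic "
            "SNP(s) with near-0.5 frequency", stacklevel=2)
        df = df[~ambiguous].copy()

    a1 = df["SNP"].map(panel["a1"])
    a2 = df["SNP"].map(panel["a2"])
    same = (df["A1"] == a1) & (df["A2"] == a2)
    swapped = (df["A1"] == a2) & (df["A2"] == a1)
    mismatched = ~(same | swapped)
    if mismatched.any():
        logger.info("read_sumstats: dropped %d SNPs with allele mismatch",
                    int(mismatched.sum()))
        df = df[~mismatched].copy()
        same, swapped = same[~mismatched], swapped[~mismatched]
    df.loc[swapped, "BETA"] = -df.loc[swapped, "BETA"]
    df.loc[swapped, "FREQ"] = 1.0 - df.loc[swapped, "FREQ"]
    df.loc[swapped, ["A1", "A2"]] = df.loc[swapped, ["A2", "A1"]].to_numpy()
    return df.reset_index(drop=True)


def write_sumstats(sumstats: pd.DataFrame, path: str | Path) -> None:
    sumstats.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tables and sidecars


def write_responses(responses: ResponseMatrix, prefix: str | Path) -> None:
    """Write accuracy/RT/bank (and truth, if simulated) as CSV files."""
    prefix = Path(prefix)
    responses.accuracy.rename_axis("subject_id").to_csv(f"{prefix}_accuracy.csv")
    responses.rt.rename_axis("subject_id").to_csv(f"{prefix}_rt.csv")
    responses.bank.to_csv(f"{prefix}_bank.csv")
    if responses.choices is not None:
        responses.choices.rename_axis("subject_id").to_csv(f"{prefix}_choices.csv")
    if responses.truth is not None:
        responses.truth.to_csv(f"{prefix}_truth.csv")


def write_twin_csv(data: TwinDataset, path: str | Path) -> None:
    data.pairs.to_csv(path, index=False)


def read_twin_csv(path: str | Path) -> TwinDataset:
    pairs = pd.read_csv(path)
    fixed = {"pair_id", "zygosity", "sex1", "sex2", "group"}
    traits = sorted({col[:-3] for col in pairs.columns
                     if col.endswith("_t1") and col not in fixed})
    if not traits:
        raise ValueError(f"{path}: no trait columns (expected <trait>_t1/_t2)")
    return TwinDataset(pairs=pairs, traits=traits)


def write_sidecar(path: str | Path, **payload) -> None:
    """Echo specs and seeds next to generated data as a YAML sidecar."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(payload, fh, default_flow_style=False, sort_keys=True)
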