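"""Shared container types used across the pipeline.

The pipeline passes a small number of in-memory containers between stages:
an item bank, a subjects-by-items response matrix, a twin-pair table, a
dosage matrix with SNP metadata, and GWAS summary statistics.  They are thin
dataclasses around pandas/numpy objects so that every stage can read and
write them through plain CSV/TSV/VCF files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_DOMAINS = ("verbal", "nonverbal")


@dataclass
class ItemSpec:
    """One test item of a two- or three-parameter logistic model.

    Parameters follow the usual IRT conventions: ``a`` is discrimination
    (slope of the characteristic curve), ``b`` difficulty (ability at which
    a non-guessing examinee answers correctly with probability 0.5) and
    ``c`` a lower asymptote for guessing (0 for the 2PL).  Quality-control
    items carry ``is_qc=True`` and are excluded from scoring.
    """

    item_id: str
    domain: str
    test: str
    a: float
    b: float
    c: float = 0.0
    time_limit: float = 30.0
    is_qc: bool = False

    def __post_init__(self) -> None:
        if self.domain not in VALID_DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.a < 0:
            raise ValueError(f"item {self.item_id}: discrimination must be >= 0")
        if not 0.0 <= self.c < 1.0:
            raise ValueError(f"item {self.item_id}: guessing must be in [0, 1)")
        if self.time_limit <= 0:
            raise ValueError(f"item {self.item_id}: time limit must be positive")


def bank_frame(bank: list[ItemSpec]) -> pd.DataFrame:
    """Item bank as a DataFrame indexed by item_id."""
    df = pd.DataFrame(
        {
            "item_id": [it.item_id for it in bank],
            "domain": [it.domain for it in bank],
            "test": [it.test for it in bank],
            "a": [it.a for it in bank],
            "b": [it.b for it in bank],
            "c": [it.c for it in bank],
            "time_limit": [it.time_limit for it in bank],
            "is_qc": [it.is_qc for it in bank],
        }
    )
    if df["item_id"].duplicated().any():
        raise ValueError("duplicate item ids in bank")
    return df.set_index("item_id")


@dataclass
class ResponseMatrix:
    """Binary accuracies plus response times for subjects x items.

    ``accuracy`` and ``rt`` share the same index (subject ids) and columns
    (item ids).  ``truth`` records the generating ability and any planted
    careless-responder status; it is only populated for simulated data.
    """

    accuracy: pd.DataFrame
    rt: pd.DataFrame
    bank: pd.DataFrame
    truth: pd.DataFrame | None = None
    choices: pd.DataFrame | None = None

    @property
    def scored_items(self) -> list[str]:
        return list(self.bank.index[~self.bank["is_qc"]])

    @property
    def qc_items(self) -> list[str]:
        return list(self.bank.index[self.bank["is_qc"]])


@dataclass
class TwinDataset:
    """Long-format twin pair table, one row per pair.

    Columns: pair_id, zygosity (MZ/DZ), sex1, sex2, group (MZm, MZf, DZm,
    DZf, DZos) and ``<trait>_t1`` / ``<trait>_t2`` value pairs for each
    trait.  ``truth`` carries the generating variance components.
    """

    pairs: pd.DataFrame
    traits: list[str]
    truth: dict = field(default_factory=dict)

    def trait_pairs(self, trait: str, zygosity: str | None = None,
                    group: str | None = None) -> np.ndarray:
        df = self.pairs
        if zygosity is not None:
            df = df[df["zygosity"] == zygosity]
        if group is not None:
            df = df[df["group"] == group]
        return df[[f"{trait}_t1", f"{trait}_t2"]].to_numpy(float)


@dataclass
class GenotypeMatrix:
    """Additive dosages (individuals x SNPs) with per-SNP metadata.

    ``snps`` columns: snp, chrom, pos (1-based), a1 (counted allele), a2,
    freq (frequency of a1).  ``missing`` flags entries that were imputed to
    twice the allele frequency on read.
    """

    ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.ids), len(self.snps)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} inconsistent with "
                f"{len(self.ids)} individuals x {len(self.snps)} SNPs"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.snps)

    def standardized(self) -> np.ndarray:
        """Dosages centred at 2p and scaled by sqrt(2p(1-p)) per SNP."""
        p = self.snps["freq"].to_numpy(float)
        sd = np.sqrt(2.0 * p * (1.0 - p))
        if np.any(sd == 0):
            bad = self.snps["snp"][sd == 0].tolist()
            raise ValueError(f"monomorphic SNPs cannot be standardized: {bad[:5]}")
        return (self.dosages - 2.0 * p) / sd
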