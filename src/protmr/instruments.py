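"""Cis-pQTL instrument selection.

Qualified instruments per protein are found by: restricting to the cis
window around the encoding gene, applying genome-wide significance,
greedy LD clumping to an approximately independent set, and filtering on
per-variant instrument strength (F-statistic).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import VariantRecord

GENOME_WIDE_P = 5e-8
CIS_WINDOW_BP = 1_000_000
CLUMP_R2 = 0.1
CLUMP_WINDOW_KB = 1000
F_MIN = 10.0

# Stricter preset used by some pipelines for instrument independence.
CLUMP_STRICT = {"r2_threshold": 0.001, "window_kb": 10_000}


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene body coordinates, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class InstrumentStats:
    """Variance explained and strength for one instrument."""

    variant_id: str
    r2: float
    f_stat: float
    k: int
    n: float


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a 4-column TSV (gene_id, chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples(index=False)]


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square LD correlation matrix TSV keyed by variant id."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    ld.columns = ld.columns.astype(str)
    return ld


def select_cis(
    records: list[VariantRecord],
    gene: GeneAnnotation,
    window_bp: int = CIS_WINDOW_BP,
) -> list[VariantRecord]:
    """Retain variants within ``window_bp`` of the gene body on its chromosome."""
    lo = gene.start - window_bp
    hi = gene.end + window_bp
    return [r for r in records if r.chrom == gene.chrom and lo <= r.pos <= hi]


def filter_pvalue(
    records: list[VariantRecord], threshold: float = GENOME_WIDE_P
) -> list[VariantRecord]:
    """Keep variants with p strictly below the significance threshold."""
    return [r for r in records if r.pval < threshold]


def ld_clump(
    records: list[VariantRecord],
    ld: pd.DataFrame,
    r2_threshold: float = CLUMP_R2,
    window_kb: int = CLUMP_WINDOW_KB,
) -> list[VariantRecord]:
    """Greedy LD clumping on p-value rank.

    Repeatedly keeps the remaining variant with the smallest p-value
    (ties broken by smaller position, then lexicographic id) and removes
    every remaining variant within ``window_kb`` of it whose squared
    correlation with it is >= ``r2_threshold``.  Kept variants are
    returned in selection order.

    Raises
    ------
    KeyError
        If any input variant is absent from the LD matrix.
    """
    missing = [r.variant_id for r in records
               if r.variant_id not in ld.index or r.variant_id not in ld.columns]
    if missing:
        raise KeyError(f"variants missing from LD matrix: {missing}")

    remaining = sorted(records, key=lambda r: (r.pval, r.pos, r.variant_id))
    kept: list[VariantRecord] = []
    window_bp = window_kb * 1000
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        survivors = []
        for r in remaining:
            if r.chrom == lead.chrom and abs(r.pos - lead.pos) <= window_bp:
                r2 = float(ld.loc[lead.variant_id, r.variant_id]) ** 2
                if r2 >= r2_threshold:
                    continue
            survivors.append(r)
        remaining = survivors
    return kept


def variance_explained(eaf: float, beta: float) -> float:
    """Per-variant trait variance explained: 2·EAF·(1−EAF)·β².

    Assumes a standardized trait and Hardy–Weinberg genotype variance.
    """
    if not 0.0 < eaf < 1.0:
        raise ValueError("EAF must lie in (0,1)")
    return 2.0 * eaf * (1.0 - eaf) * beta ** 2


def f_statistic(
    r2: float,
    n: float,
    k: int = 1,
    formula_variant: str = "standard",
) -> float:
    """Instrument-strength F-statistic.

    ``standard``:   F = R²(N−K−1) / ((1−R²)K)  (two-stage least squares).
    ``as_printed``: F = R²(N−K−1) / ((1+R²)K)  (alternative denominator,
    retained as a configurable variant for auditability).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    if formula_variant == "standard":
        denom = (1.0 - r2) * k
    elif formula_variant == "as_printed":
        denom = (1.0 + r2) * k
    else:
        raise ValueError(f"unknown formula_variant {formula_variant!r}")
    return r2 * (n - k - 1) / denom


def instrument_stats(
    records: list[VariantRecord],
    formula_variant: str = "standard",
) -> list[InstrumentStats]:
    """Per-variant R² and F (K=1) for a set of clumped instruments."""
    return [
        InstrumentStats(
            r.variant_id,
            r2 := variance_explained(r.eaf, r.beta),
            f_statistic(r2, r.n, 1, formula_variant),
            1,
            r.n,
        )
        for r in records
    ]


def overall_f(records: list[VariantRecord], formula_variant: str = "standard") -> float:
    """Multi-instrument F with K = instrument count, R² = sum of per-variant R²."""
    k = len(records)
    if k == 0:
        raise ValueError("no instruments")
    r2 = sum(variance_explained(r.eaf, r.beta) for r in records)
    n = min(r.n for r in records)
    return f_statistic(r2, n, k, formula_variant)


def filter_weak(
    instruments: list[InstrumentStats], f_min: float = F_MIN
) -> list[InstrumentStats]:
    """Keep instruments with F strictly above ``f_min``.

    A protein left with zero instruments has no qualified instrument and
    is excluded from MR (the caller flags it).
    """
    return [i for i in instruments if i.f_stat > f_min]
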