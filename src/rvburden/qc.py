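"""Genotype-level quality control and the iterative call-rate filter.

Per-call filters follow the usual exome-pipeline conventions: VQSR
pass/fail at the site level, depth bounds, genotype-class-specific rules
on genotype quality, hom-ref likelihood and allele depths, and an exact
binomial allele-balance test for heterozygotes. Thresholds are strict
inequalities ("lower than 10" removes DP = 9 and keeps DP = 10).

Call-rate filtering runs in three fixed passes: variants < 90%, then
samples < 95%, then variants < 95%, each rate computed over what the
previous pass retained.

Sample-level exclusions (sex mismatch, duplicates, ancestry outliers,
contamination, chimeric reads, relatedness) require raw reads or
genome-wide genotypes and are consumed as precomputed boolean flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeCall",
    "allele_balance_p",
    "filter_genotype",
    "iterative_callrate_filter",
    "apply_sample_flags",
    "qc_report",
]

AB_P_THRESHOLD = 1e-9


@dataclass
class GenotypeCall:
    """One sample x variant genotype call with its QC metrics."""

    sample_id: str
    variant_id: str
    genotype: str  # hom_ref | het | hom_alt | missing
    dp: int
    gq: int
    pl_homref: int
    ad_ref: int
    ad_alt: int
    vqsr_pass: bool = True

    def __post_init__(self) -> None:
        if self.genotype not in ("hom_ref", "het", "hom_alt", "missing"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        for name in ("dp", "gq", "pl_homref", "ad_ref", "ad_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ad_ref + self.ad_alt > self.dp:
            raise ValueError("ad_ref + ad_alt exceeds read depth")


def allele_balance_p(ad_alt: int, ad_ref: int) -> float:
    """Two-tailed exact binomial probability of an allele split at least
    as extreme as observed under a fair (p = 0.5) split.

    Undefined for zero informative reads; callers remove such calls by
    the informative-reads rule instead.
    """
    n = ad_alt + ad_ref
    if n <= 0:
        raise ValueError("allele_balance_p requires at least one informative read")
    return float(stats.binomtest(ad_alt, n, 0.5, alternative="two-sided").pvalue)


def filter_genotype(c: GenotypeCall) -> tuple[bool, list[str]]:
    """Evaluate every genotype-level filter; returns (keep, reasons).

    ``reasons`` lists every violated rule, not just the first:
    site VQSR fail; DP < 10 or > 1000; hom-ref GQ < 25; hom-alt
    PL(HomRef) < 25 or alt reads < 90% of depth; het PL(HomRef) < 25,
    alt fraction < 25% of informative reads, informative reads < 90% of
    depth, or allele-balance p < 1e-9.
    """
    reasons: list[str] = []
    if not c.vqsr_pass:
        reasons.append("vqsr_fail")
    if c.dp < 10:
        reasons.append("low_dp")
    elif c.dp > 1000:
        reasons.append("high_dp")

    if c.genotype == "hom_ref":
        if c.gq < 25:
            reasons.append("homref_low_gq")
    elif c.genotype == "hom_alt":
        if c.pl_homref < 25:
            reasons.append("homalt_low_pl_homref")
        if c.ad_alt < 0.9 * c.dp:
            reasons.append("homalt_low_alt_fraction")
    elif c.genotype == "het":
        informative = c.ad_ref + c.ad_alt
        if c.pl_homref < 25:
            reasons.append("het_low_pl_homref")
        if informative > 0 and c.ad_alt < 0.25 * informative:
            reasons.append("het_low_alt_fraction")
        if informative < 0.9 * c.dp:
            reasons.append("het_low_informative_reads")
        if informative > 0 and allele_balance_p(c.ad_alt, c.ad_ref) < AB_P_THRESHOLD:
            reasons.append("het_allele_balance")
    return len(reasons) == 0, reasons


def iterative_callrate_filter(
    calls: pd.DataFrame,
) -> tuple[list[str], list[str]]:
    """Three-pass call-rate filter on a sample x variant presence matrix.

    ``calls`` is a boolean DataFrame (index samples, columns variants)
    where True means the genotype survived per-call QC. Passes, in
    order: drop variants with call rate < 0.90, drop samples with call
    rate < 0.95, drop variants with call rate < 0.95; every rate is
    recomputed over the rows/columns still retained.

    Returns (retained_samples, retained_variants); both may be empty.
    """
    if calls.shape[0] == 0 or calls.shape[1] == 0:
        return list(calls.index), list(calls.columns)
    m = calls.astype(bool)

    variant_rate = m.mean(axis=0)
    m = m.loc[:, variant_rate >= 0.90]
    if m.shape[1] == 0:
        return list(m.index), []

    sample_rate = m.mean(axis=1)
    m = m.loc[sample_rate >= 0.95, :]
    if m.shape[0] == 0:
        return [], list(m.columns)

    variant_rate = m.mean(axis=0)
    m = m.loc[:, variant_rate >= 0.95]
    return list(m.index), list(m.columns)


SAMPLE_FLAG_NAMES = (
    "sex_mismatch",
    "duplicate",
    "ancestry_outlier",
    "contamination",
    "chimeras",
    "relatedness",
)


def apply_sample_flags(
    samples: Sequence[str], flags: Mapping[str, Mapping[str, bool]]
) -> list[str]:
    """Drop any sample with a true exclusion flag.

    ``flags`` maps sample id -> {flag name: bool}; every sample must be
    covered. The relatedness flag is expected to mark exactly one member
    of each related pair (pi-hat >= 0.2), decided upstream.
    """
    missing = [s for s in samples if s not in flags]
    if missing:
        raise ValueError(f"missing QC flags for samples: {missing[:5]}")
    retained = []
    for s in samples:
        if not any(bool(flags[s].get(name, False)) for name in SAMPLE_FLAG_NAMES):
            retained.append(s)
    return retained


def qc_report(calls: Iterable[GenotypeCall]) -> pd.DataFrame:
    """Per-call QC table: sample, variant, keep flag and the violated
    rules joined with ';' (empty when the call passes)."""
    rows = []
    for c in calls:
        keep, reasons = filter_genotype(c)
        rows.append(
            {
                "sample_id": c.sample_id,
                "variant_id": c.variant_id,
                "keep": keep,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "variant_id", "keep", "reasons"])
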