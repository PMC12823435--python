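"""Harmonized case vs (internal + external) control gene discovery.

The discovery procedure compares per-gene counts of qualifying rare
class I (PTV + severe missense) and class II (moderate missense)
variants between cases and a control group enlarged with an external
reference cohort sequenced elsewhere. Because the two datasets differ in
capture and calling, three harmonization steps precede any testing:

1. coverage masking — only regions where >= 80% of samples reach 10x
   coverage in *both* datasets are analysed;
2. synonymous-rate calibration — genes where cases show a rate of rare
   synonymous variants at or above controls are excluded, since a
   deleterious-variant excess there could reflect dataset artefacts;
3. direction restriction — only genes with a strictly higher case rate
   of the tested class are tested, the complement being uninterpretable
   after step 2.

Each retained gene/class is tested with a two-tailed Fisher's exact
test; genes qualifying in both classes are additionally meta-analysed
with a weighted z-score combination, and reported at the minimum p of
their three tests. Multiple-testing accounting counts every calibrated
gene once plus two extra tests per dual-class gene.

The X-chromosome variant of the procedure tests carrier counts
stratified by sex (female, male, combined) and counts only
direction-passing genes: 3 tests per class-qualifying gene plus one
meta test per dual gene, with a fixed class-II/class-I weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneTestResult",
    "high_confidence_mask",
    "combine_control_counts",
    "synonymous_calibration_filter",
    "direction_filter",
    "gene_fisher",
    "haldane_odds_ratio",
    "weighted_z_meta",
    "count_tests",
    "run_autosomal_discovery",
    "run_x_discovery",
]

MIN_P = float(np.nextafter(0, 1))

COUNT_COLUMNS = [
    "gene_id",
    "case_class_I",
    "control_class_I",
    "case_class_II",
    "control_class_II",
    "case_synonymous",
    "control_synonymous",
]


@dataclass
class GeneTestResult:
    """One per-gene, per-class discovery result."""

    gene_id: str
    test_class: str  # class_I | class_II | meta
    odds_ratio: float  # may be inf (control cell 0) or nan (empty table)
    p_value: float
    table: tuple[int, int, int, int]  # case_count, case_rest, control_count, control_rest
    components: dict = field(default_factory=dict)
    empty: bool = False


def high_confidence_mask(
    coverage_internal: Mapping[str, float],
    coverage_external: Mapping[str, float],
    min_fraction: float = 0.80,
) -> tuple[set[str], list[str]]:
    """Regions callable in both datasets.

    A region is retained iff the fraction of samples with >= 10x
    coverage is >= ``min_fraction`` in *both* summaries (inclusive at
    the boundary). Regions present in only one summary are excluded and
    returned separately for logging.

    Returns ``(retained, unmatched)``.
    """
    internal = dict(coverage_internal)
    external = dict(coverage_external)
    unmatched = sorted(set(internal) ^ set(external))
    retained = {
        r
        for r in set(internal) & set(external)
        if internal[r] >= min_fraction and external[r] >= min_fraction
    }
    return retained, unmatched


def combine_control_counts(
    genes: pd.DataFrame,
    external: pd.DataFrame,
    n_control_internal: int,
    n_control_external: int,
) -> pd.DataFrame:
    """Add external-control allele counts to the internal control cells.

    ``external`` has the same per-class count columns with a
    ``control_`` prefix (genes absent from it contribute zero). Returns
    a copy with combined control counts and attrs recording the total
    control sample size.
    """
    out = genes.copy()
    ext = external.set_index("gene_id")
    for cls in ("class_I", "class_II", "synonymous"):
        col = f"control_{cls}"
        add = out["gene_id"].map(ext[col]).fillna(0).astype(int) if col in ext else 0
        out[col] = out[col] + add
    out.attrs["n_control"] = n_control_internal + n_control_external
    return out


def synonymous_calibration_filter(
    genes: pd.DataFrame, n_case: int, n_control: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep genes whose rare synonymous rate is strictly higher in
    controls than in cases; ties are excluded.

    Returns ``(retained, excluded)``.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("sample sizes must be positive")
    case_rate = genes["case_synonymous"] / n_case
    control_rate = genes["control_synonymous"] / n_control
    keep = control_rate > case_rate
    return genes.loc[keep].copy(), genes.loc[~keep].copy()


def direction_filter(
    genes: pd.DataFrame, n_case: int, n_control: int
) -> dict[str, pd.Index]:
    """Per-class sets of genes with a strictly higher case rate.

    Returns a dict with keys ``class_I``, ``class_II`` and ``dual``
    (genes passing in both classes, eligible for meta-analysis); values
    are indexes into ``genes``.
    """
    sets: dict[str, pd.Index] = {}
    for cls in ("class_I", "class_II"):
        case_rate = genes[f"case_{cls}"] / n_case
        control_rate = genes[f"control_{cls}"] / n_control
        sets[cls] = genes.index[case_rate > control_rate]
    sets["dual"] = sets["class_I"].intersection(sets["class_II"])
    return sets


def gene_fisher(
    case_count: int,
    control_count: int,
    n_case: int,
    n_control: int,
    unit: str = "alleles",
    gene_id: str = "",
    test_class: str = "class_I",
) -> GeneTestResult:
    """Two-tailed Fisher's exact test on one gene's 2x2 table.

    Exposure per group is ``2 n`` for the allele unit (each diploid
    individual contributes two chromosomes; hemizygous male X non-PAR
    alleles are up-counted to two upstream) or ``n`` for the carrier
    unit. The odds ratio is the cross-product ratio: +inf when the
    control cell is 0 and the case cell positive, NaN (with ``empty``
    set and p = 1) when both cells are 0.
    """
    if unit not in ("alleles", "carriers"):
        raise ValueError(f"unknown unit {unit!r}")
    exposure_case = 2 * n_case if unit == "alleles" else n_case
    exposure_control = 2 * n_control if unit == "alleles" else n_control
    if case_count > exposure_case or control_count > exposure_control:
        raise ValueError("count exceeds group exposure")
    a, b = int(case_count), exposure_case - int(case_count)
    c, d = int(control_count), exposure_control - int(control_count)
    if a == 0 and c == 0:
        return GeneTestResult(gene_id, test_class, float("nan"), 1.0, (a, b, c, d), empty=True)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if c == 0 or b == 0:
        or_ = float("inf")
    elif a == 0 or d == 0:
        or_ = 0.0
    else:
        or_ = (a * d) / (b * c)
    return GeneTestResult(gene_id, test_class, float(or_), float(p), (a, b, c, d))


def haldane_odds_ratio(table: tuple[int, int, int, int]) -> float:
    """Haldane–Anscombe (add 0.5 to every cell) odds ratio; finite even
    with empty cells, used for plotting alongside the raw OR."""
    a, b, c, d = (x + 0.5 for x in table)
    return (a * d) / (b * c)


def weighted_z_meta(p1: float, p2: float, w1: float, w2: float) -> float:
    """Weighted z-score combination of two p-values.

    Two-tailed input p-values are converted to one-sided z-scores
    (z = Phi^-1(1 - p/2); the direction restriction upstream guarantees
    both tests point toward case enrichment), combined as
    ``(w1 z1 + w2 z2) / sqrt(w1^2 + w2^2)`` and returned as the
    upper-tail probability. Zero p-values are clamped to the smallest
    positive float.
    """
    if w1 <= 0 or w2 <= 0:
        raise ValueError("weights must be positive")
    ps = []
    for p in (p1, p2):
        if not (0 <= p <= 1):
            raise ValueError(f"p-value {p} outside [0, 1]")
        ps.append(max(p, MIN_P))
    z1, z2 = (stats.norm.isf(p / 2) for p in ps)
    z_meta = (w1 * z1 + w2 * z2) / math.hypot(w1, w2)
    return float(stats.norm.sf(z_meta))


def count_tests(n_filtered_genes: int, n_dual_genes: int) -> tuple[int, float]:
    """Autosomal test accounting: every calibrated gene is one test and
    each dual-class gene adds two more (second class + meta). Returns
    ``(n_tests, bonferroni_alpha)``."""
    if n_dual_genes > n_filtered_genes:
        raise ValueError("dual-class genes cannot exceed filtered genes")
    n_tests = n_filtered_genes + 2 * n_dual_genes
    return n_tests, 0.05 / n_tests


def run_autosomal_discovery(
    genes: pd.DataFrame,
    n_case: int,
    n_control: int,
    unit: str = "alleles",
    meta_weights: tuple[float, float] = (1.0, 1.0),
    n_calibrated: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Direction-restricted per-gene discovery with dual-class meta.

    ``genes`` must already have passed the coverage mask and the
    synonymous calibration filter. Class I genes are tested on class I
    counts, class II genes on class II counts; dual genes additionally
    get a weighted z meta of their two (one-sided-converted) p-values
    with ``meta_weights = (w_class_I, w_class_II)`` and are reported at
    the minimum p across their three tests.

    ``n_calibrated`` (default ``len(genes)``) is the number of
    calibrated genes entering the multiple-testing account.

    Returns a ranked results DataFrame (one row per gene with its best
    test plus per-test detail rows in ``all_tests``) and a metadata dict
    with the test count, alpha and filter tallies.
    """
    n_calibrated = len(genes) if n_calibrated is None else n_calibrated
    sets = direction_filter(genes, n_case, n_control)
    dual = set(sets["dual"])
    n_tests, alpha = count_tests(n_calibrated, len(dual))

    detail: list[GeneTestResult] = []
    per_gene: dict[str, list[GeneTestResult]] = {}
    for cls in ("class_I", "class_II"):
        for idx in sets[cls]:
            row = genes.loc[idx]
            res = gene_fisher(
                row[f"case_{cls}"],
                row[f"control_{cls}"],
                n_case,
                n_control,
                unit=unit,
                gene_id=row["gene_id"],
                test_class=cls,
            )
            detail.append(res)
            per_gene.setdefault(row["gene_id"], []).append(res)
    w1, w2 = meta_weights
    for idx in sets["dual"]:
        gid = genes.loc[idx, "gene_id"]
        r1, r2 = per_gene[gid]
        p_meta = weighted_z_meta(r1.p_value, r2.p_value, w1, w2)
        meta = GeneTestResult(
            gid,
            "meta",
            haldane_odds_ratio(r1.table),
            p_meta,
            r1.table,
            components={
                "p_class_I": r1.p_value,
                "p_class_II": r2.p_value,
                "w_class_I": w1,
                "w_class_II": w2,
            },
        )
        detail.append(meta)
        per_gene[gid].append(meta)

    rows = []
    for gid, results in per_gene.items():
        best = min(results, key=lambda r: r.p_value)
        rows.append(
            {
                "gene_id": gid,
                "best_class": best.test_class,
                "odds_ratio": best.odds_ratio,
                "p_value": best.p_value,
                "n_tests_gene": len(results),
                "significant": best.p_value < alpha,
            }
        )
    ranked = pd.DataFrame(
        rows, columns=["gene_id", "best_class", "odds_ratio", "p_value", "n_tests_gene", "significant"]
    )
    if len(ranked):
        # deterministic rank: p ascending, then OR descending, then gene id
        or_key = ranked["odds_ratio"].fillna(0.0)
        ranked = (
            ranked.assign(_or=-or_key)
            .sort_values(["p_value", "_or", "gene_id"], kind="mergesort")
            .drop(columns="_or")
            .reset_index(drop=True)
        )
    meta_info = {
        "n_calibrated_genes": int(n_calibrated),
        "n_class_I_genes": int(len(sets["class_I"])),
        "n_class_II_genes": int(len(sets["class_II"])),
        "n_dual_genes": int(len(dual)),
        "n_tests": int(n_tests),
        "alpha": float(alpha),
        "unit": unit,
        "meta_weights": [float(w1), float(w2)],
        "p_side": "one-sided after enforced enrichment direction (meta); two-tailed Fisher otherwise",
    }
    meta_info["all_tests"] = detail
    return ranked, meta_info


def run_x_discovery(
    carriers: pd.DataFrame,
    n_case: Mapping[str, int],
    n_control: Mapping[str, int],
    weight_class_II: float = 0.55,
) -> tuple[pd.DataFrame, dict]:
    """X-chromosome carrier-based discovery, sex-stratified.

    ``carriers`` has one row per (gene_id, class) with carrier counts
    ``case_female, case_male, control_female, control_male``; genes must
    already pass calibration, direction restriction and the scaled
    non-PAR rarity threshold. ``n_case`` / ``n_control`` map
    ``"female"``/``"male"`` to group sizes.

    Per gene and class, three carrier Fisher tests are run (female,
    male, combined). Genes present in both classes also get a weighted z
    meta of the two combined-sex p-values with fixed weights
    ``(1, weight_class_II)``. Total tests = 3 per class-qualifying gene
    plus 1 per dual gene; Bonferroni alpha = 0.05 / total.
    """
    required = {"gene_id", "test_class", "case_female", "case_male", "control_female", "control_male"}
    missing = required - set(carriers.columns)
    if missing:
        raise ValueError(f"carriers table missing columns {sorted(missing)}")

    nf_case, nm_case = int(n_case["female"]), int(n_case["male"])
    nf_ctl, nm_ctl = int(n_control["female"]), int(n_control["male"])

    rows = []
    combined_p: dict[tuple[str, str], float] = {}
    for _, row in carriers.iterrows():
        gid, cls = row["gene_id"], row["test_class"]
        strata = {
            "female": (row["case_female"], row["control_female"], nf_case, nf_ctl),
            "male": (row["case_male"], row["control_male"], nm_case, nm_ctl),
            "combined": (
                row["case_female"] + row["case_male"],
                row["control_female"] + row["control_male"],
                nf_case + nm_case,
                nf_ctl + nm_ctl,
            ),
        }
        for stratum, (a, c, n1, n0) in strata.items():
            res = gene_fisher(a, c, n1, n0, unit="carriers", gene_id=gid, test_class=cls)
            rows.append(
                {
                    "gene_id": gid,
                    "test_class": cls,
                    "stratum": stratum,
                    "odds_ratio": res.odds_ratio,
                    "p_value": res.p_value,
                }
            )
            if stratum == "combined":
                combined_p[(gid, cls)] = res.p_value

    by_gene: dict[str, set[str]] = {}
    for gid, cls in combined_p:
        by_gene.setdefault(gid, set()).add(cls)
    dual_genes = sorted(g for g, classes in by_gene.items() if classes == {"class_I", "class_II"})
    for gid in dual_genes:
        p_meta = weighted_z_meta(
            combined_p[(gid, "class_I")], combined_p[(gid, "class_II")], 1.0, weight_class_II
        )
        rows.append(
            {
                "gene_id": gid,
                "test_class": "meta",
                "stratum": "combined",
                "odds_ratio": float("nan"),
                "p_value": p_meta,
            }
        )

    n_class = {
        cls: sum(1 for (_, c) in combined_p if c == cls) for cls in ("class_I", "class_II")
    }
    n_tests = 3 * n_class["class_I"] + 3 * n_class["class_II"] + len(dual_genes)
    alpha = 0.05 / n_tests if n_tests else float("nan")
    results = pd.DataFrame(rows)
    if len(results):
        results["significant"] = results["p_value"] < alpha
        results = results.sort_values(
            ["p_value", "gene_id", "test_class", "stratum"], kind="mergesort"
        ).reset_index(drop=True)
    info = {
        "n_class_I_genes": n_class["class_I"],
        "n_class_II_genes": n_class["class_II"],
        "n_dual_genes": len(dual_genes),
        "n_tests": int(n_tests),
        "alpha": float(alpha),
        "weight_class_II": float(weight_class_II),
    }
    return results, info
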