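"""Synthetic case-control exome cohorts for pipeline testing.

The restricted source data (registry-ascertained cases, external
reference controls) cannot ship with the package, so every downstream
stage is exercised on synthetic cohorts with the statistical structure
the analysis assumes:

* per-(individual, gene, class) rare-allele counts are independent
  Poisson draws — rare-variant counts are sparse and every model in the
  pipeline operates on counts, not haplotypes;
* case enrichment is planted by exponential tilting: cases draw counts
  at ``baseline_rate x OR`` in risk genes, which makes the planted
  per-allele odds ratio exactly identifiable by case-control logistic
  regression on counts (Poisson(lambda e^beta) / Poisson(lambda)
  likelihood ratio is exp(beta x) up to a constant);
* covariates (sex, birth year, PCs, sequencing wave, coverage metrics)
  are drawn with configurable case-control mean shifts; a polygenic
  score is drawn with a standardized case shift;
* comorbidity labels are Bernoulli within cases, and comorbid cases
  carry an extra rate multiplier in configured gene sets;
* the external control set has its own coverage mask (a configurable
  fraction of genes drops below the 80% x 10x threshold) and a
  multiplicative distortion of its synonymous rates, so the coverage
  and synonymous-calibration harmonization steps have real work to do.

One master seed expands into named per-component streams, so the same
configuration always produces a bit-identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_cohort",
    "simulate_gene_counts",
    "simulate_genotype_calls",
    "simulate_clinical_iq",
    "attach_outcomes",
    "DEFAULT_BASELINE_RATES",
    "DEFAULT_COMORBIDITY_MODEL",
]

CLASSES = ("class_I", "class_II", "synonymous")

# Per-gene, per-individual expected rare allele counts. Chosen so that a
# genome-scale gene panel reproduces realistic per-person totals
# (roughly one rare PTV-class allele and ~10 rare synonymous alleles per
# exome when summed over ~19k genes).
DEFAULT_BASELINE_RATES = {"class_I": 6e-5, "class_II": 1e-4, "synonymous": 5e-4}

# Comorbidity prevalences among cases follow the registry frequencies of
# ID, autism, schizophrenia, substance use, disruptive behaviour and any
# additional psychiatric morbidity in a large ADHD case sample.
DEFAULT_COMORBIDITY_MODEL: dict[str, tuple[float, dict[str, float]]] = {
    "ID": (0.186, {}),
    "ASD": (0.307, {}),
    "SCZ": (0.046, {}),
    "SUD": (0.135, {}),
    "DBD": (0.116, {}),
    "multimorbidity": (0.609, {}),
}

_STREAMS = (
    "genes",
    "counts",
    "covariates",
    "pgs",
    "comorbidity",
    "external",
    "coverage",
    "outcomes",
)


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic cohort."""

    n_cases: int = 1000
    n_controls: int = 1000
    n_external_controls: int = 5000
    n_genes: int = 500
    fraction_constrained: float = 0.15
    risk_genes: Sequence[tuple[int, float]] = ()
    baseline_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RATES)
    )
    rate_dispersion: float = 0.5  # CV of the per-gene gamma rate multiplier; 0 disables
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    pgs_case_shift: float = 0.4
    comorbidity_model: Mapping[str, tuple[float, Mapping[str, float]]] = field(
        default_factory=lambda: {k: (p, dict(e)) for k, (p, e) in DEFAULT_COMORBIDITY_MODEL.items()}
    )
    gene_sets: Mapping[str, Sequence[int]] = field(default_factory=dict)
    coverage_dropout: float = 0.05
    synonymous_perturbation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_external_controls", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.fraction_constrained <= 1:
            raise ValueError("fraction_constrained must be in [0, 1]")
        if not 0 <= self.coverage_dropout <= 1:
            raise ValueError("coverage_dropout must be in [0, 1]")
        if self.synonymous_perturbation <= 0:
            raise ValueError("synonymous_perturbation must be > 0")
        if self.rate_dispersion < 0:
            raise ValueError("rate_dispersion must be >= 0")
        for cls, rate in self.baseline_rates.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown variant class {cls!r}")
            if rate < 0:
                raise ValueError("baseline rates must be >= 0")
        for idx, or_ in self.risk_genes:
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"risk gene index {idx} out of range (n_genes={self.n_genes})")
            if or_ <= 0:
                raise ValueError("risk-gene odds ratios must be > 0")
        for name, genes in self.gene_sets.items():
            for g in genes:
                if not 0 <= g < self.n_genes:
                    raise ValueError(f"gene set {name!r} references gene {g} out of range")
        for name, (prev, enrich) in self.comorbidity_model.items():
            if not 0 <= prev <= 1:
                raise ValueError(f"comorbidity {name!r} prevalence outside [0, 1]")
            for set_name, or_ in enrich.items():
                if set_name not in self.gene_sets and set_name != "constrained":
                    raise ValueError(f"comorbidity {name!r} enriches unknown gene set {set_name!r}")
                if or_ <= 0:
                    raise ValueError("comorbidity enrichment ORs must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["risk_genes"] = [[int(i), float(o)] for i, o in self.risk_genes]
        d["gene_sets"] = {k: [int(g) for g in v] for k, v in self.gene_sets.items()}
        # JSON-canonical form (tuples -> lists) so truth round-trips
        d["comorbidity_model"] = {
            k: [float(p), {s: float(o) for s, o in e.items()}]
            for k, (p, e) in self.comorbidity_model.items()
        }
        return d


@dataclass
class SyntheticDataset:
    """A simulated cohort with its external-control dataset and truth."""

    cohort: pd.DataFrame  # one row per individual: phenotype, covariates, set counts
    counts: pd.DataFrame  # long: individual_id, gene_id, vclass, count
    genes: pd.DataFrame  # gene_id, pli, constrained
    external_counts: pd.DataFrame  # gene_id, control_<class> counts
    n_external: int
    coverage: pd.DataFrame  # gene_id, coverage_internal, coverage_external
    truth: dict


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _gene_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    n_constrained = int(round(config.fraction_constrained * n))
    constrained = np.zeros(n, dtype=bool)
    constrained[:n_constrained] = True
    pli = np.where(constrained, rng.uniform(0.9, 1.0, n), rng.uniform(0.0, 0.9, n))
    return pd.DataFrame({"gene_id": gene_ids, "pli": pli, "constrained": constrained})


def _per_gene_rates(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Baseline per-gene rates with optional gamma dispersion (mean 1)."""
    rates = {}
    for cls in CLASSES:
        base = float(config.baseline_rates.get(cls, 0.0))
        lam = np.full(config.n_genes, base)
        if config.rate_dispersion > 0 and base > 0:
            shape = 1.0 / config.rate_dispersion**2
            lam = lam * rng.gamma(shape, 1.0 / shape, size=config.n_genes)
        rates[cls] = lam
    return rates


def _assign_alleles(
    rng: np.random.Generator,
    totals: np.ndarray,
    gene_ids: np.ndarray,
    individual_ids: np.ndarray,
    vclass: str,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Distribute per-gene allele totals over individuals.

    Each allele lands on an individual independently (uniformly, or
    with probability proportional to ``weights``), which is exactly the
    conditional law of independent per-individual Poisson counts given
    the gene total.
    """
    total = int(totals.sum())
    if total == 0:
        return pd.DataFrame(columns=["individual_id", "gene_id", "vclass", "count"])
    gene_rep = np.repeat(gene_ids, totals)
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        p = w / w.sum()
    chosen = rng.choice(individual_ids, size=total, p=p)
    df = pd.DataFrame({"individual_id": chosen, "gene_id": gene_rep})
    out = df.groupby(["individual_id", "gene_id"], sort=False).size().reset_index(name="count")
    out["vclass"] = vclass
    return out[["individual_id", "gene_id", "vclass", "count"]]


def simulate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset from ``config``.

    Deterministic in ``config.seed``; identical configs give
    bit-identical outputs.
    """
    rngs = _streams(config.seed)
    genes = _gene_frame(config, rngs["genes"])
    rates = _per_gene_rates(config, rngs["genes"])
    gene_ids = genes["gene_id"].to_numpy()

    n_case, n_ctl = config.n_cases, config.n_controls
    case_ids = np.array([f"case_{i:06d}" for i in range(n_case)])
    ctl_ids = np.array([f"ctl_{i:06d}" for i in range(n_ctl)])

    # --- covariates, PGS, comorbidity flags -------------------------------
    rng_cov = rngs["covariates"]
    n_total = n_case + n_ctl
    status = np.concatenate([np.ones(n_case, dtype=int), np.zeros(n_ctl, dtype=int)])
    cohort = pd.DataFrame(
        {
            "individual_id": np.concatenate([case_ids, ctl_ids]),
            "status": status,
        }
    )
    cohort["sex"] = np.where(rng_cov.random(n_total) < 0.5, "male", "female")
    cohort["birth_year"] = rng_cov.integers(1981, 2009, n_total)
    for i in range(1, 11):
        cohort[f"PC{i}"] = rng_cov.normal(0, 1, n_total)
    wave = rng_cov.integers(0, 3, n_total)
    for w in range(3):
        cohort[f"wave_{w}"] = (wave == w).astype(int)
    cohort["pct_target_20x"] = rng_cov.uniform(0.9, 0.99, n_total)
    cohort["mean_depth"] = rng_cov.normal(80, 8, n_total)
    for name, shift in config.covariate_effects.items():
        if name not in cohort.columns:
            raise ValueError(f"covariate_effects references unknown covariate {name!r}")
        cohort[name] = cohort[name] + shift * status
    cohort["pgs"] = rngs["pgs"].normal(0, 1, n_total) + config.pgs_case_shift * status

    rng_com = rngs["comorbidity"]
    for name, (prev, _) in config.comorbidity_model.items():
        flag = np.zeros(n_total, dtype=int)
        flag[:n_case] = (rng_com.random(n_case) < prev).astype(int)
        cohort[name] = flag

    # --- per-individual counts --------------------------------------------
    rng_counts = rngs["counts"]
    risk = dict(config.risk_genes)
    named_sets = {name: set(idx) for name, idx in config.gene_sets.items()}
    named_sets.setdefault("constrained", set(np.flatnonzero(genes["constrained"].to_numpy())))
    enriched_by_gene: dict[int, list[tuple[str, str]]] = {}
    for com, (_, enrich) in config.comorbidity_model.items():
        for set_name in enrich:
            for g in named_sets[set_name]:
                enriched_by_gene.setdefault(g, []).append((com, set_name))

    frames = []
    for cls in CLASSES:
        lam = rates[cls]
        case_lam = lam.copy()
        if cls == "class_I":
            for g, or_ in risk.items():
                case_lam[g] = lam[g] * or_
        plain = np.array([g not in enriched_by_gene for g in range(config.n_genes)])
        plain_or_syn = plain | (cls == "synonymous")

        # controls: uniform assignment everywhere
        totals = rng_counts.poisson(lam * n_ctl)
        frames.append(_assign_alleles(rng_counts, totals, gene_ids, ctl_ids, cls))
        # cases, genes without comorbidity enrichment
        totals = rng_counts.poisson(case_lam * n_case * plain_or_syn)
        frames.append(_assign_alleles(rng_counts, totals, gene_ids, case_ids, cls))
        # cases, comorbidity-enriched genes: per-individual rate multipliers
        if not np.all(plain_or_syn):
            flags = {c: cohort.loc[: n_case - 1, c].to_numpy() for c in config.comorbidity_model}
            for g in np.flatnonzero(~plain_or_syn):
                w = np.ones(n_case)
                for com, set_name in enriched_by_gene[g]:
                    or_c = config.comorbidity_model[com][1][set_name]
                    w = w * np.where(flags[com] == 1, or_c, 1.0)
                total = rng_counts.poisson(case_lam[g] * w.sum())
                frames.append(
                    _assign_alleles(
                        rng_counts,
                        np.array([total]),
                        gene_ids[[g]],
                        case_ids,
                        cls,
                        weights=w,
                    )
                )
    counts = pd.concat(frames, ignore_index=True)
    counts = (
        counts.groupby(["individual_id", "gene_id", "vclass"], sort=True)["count"]
        .sum()
        .reset_index()
    )
    counts["count"] = counts["count"].astype(np.int64)

    # per-individual covariate totals derived from the realized counts
    per_person = counts.pivot_table(
        index="individual_id", columns="vclass", values="count", aggfunc="sum", fill_value=0
    )
    for cls in CLASSES:
        if cls not in per_person:
            per_person[cls] = 0
    cohort["n_synonymous_rare"] = (
        cohort["individual_id"].map(per_person["synonymous"]).fillna(0).astype(int)
    )
    cohort["n_variants_total"] = (
        cohort["individual_id"].map(per_person.sum(axis=1)).fillna(0).astype(int)
    )

    # per-gene-set count columns (used directly by the burden models)
    for set_name, idx in named_sets.items():
        set_genes = set(gene_ids[sorted(idx)])
        for cls in CLASSES:
            sub = counts[(counts["vclass"] == cls) & counts["gene_id"].isin(set_genes)]
            per = sub.groupby("individual_id")["count"].sum()
            cohort[f"{set_name}_{cls}"] = (
                cohort["individual_id"].map(per).fillna(0).astype(int)
            )

    # --- external controls (aggregate counts) ------------------------------
    rng_ext = rngs["external"]
    n_ext = config.n_external_controls
    ext = {"gene_id": gene_ids}
    for cls in CLASSES:
        lam = rates[cls].copy()
        if cls == "synonymous":
            lam = lam * config.synonymous_perturbation
        ext[f"control_{cls}"] = rng_ext.poisson(lam * n_ext)
    external_counts = pd.DataFrame(ext)

    # --- coverage summaries -------------------------------------------------
    rng_covg = rngs["coverage"]
    cov_int = rng_covg.uniform(0.85, 1.0, config.n_genes)
    dropout = rng_covg.random(config.n_genes) < config.coverage_dropout
    cov_ext = np.where(
        dropout,
        rng_covg.uniform(0.30, 0.79, config.n_genes),
        rng_covg.uniform(0.85, 1.0, config.n_genes),
    )
    coverage = pd.DataFrame(
        {"gene_id": gene_ids, "coverage_internal": cov_int, "coverage_external": cov_ext}
    )

    return SyntheticDataset(
        cohort=cohort,
        counts=counts,
        genes=genes,
        external_counts=external_counts,
        n_external=n_ext,
        coverage=coverage,
        truth=config.to_dict(),
    )


def simulate_gene_counts(
    n_case: int,
    n_control: int,
    n_genes: int,
    baseline_rates: Mapping[str, float] | None = None,
    risk_genes: Sequence[tuple[int, float]] = (),
    rate_dispersion: float = 0.5,
    synonymous_perturbation: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Aggregate per-gene count table (no per-individual structure).

    Fast path for gene-discovery simulations at realistic sample sizes:
    each (gene, class, group) total is one binomial draw over the
    group's allele exposure (2n chromosomes, per-chromosome frequency
    rate/2), with the case frequency tilted by the planted odds ratio
    in risk genes. Binomial rather than Poisson sampling keeps counts
    within the exposure bound at any rate, so the conditional law of a
    count given the gene's allele total is exactly the hypergeometric
    null of Fisher's test. Columns match :mod:`rvburden.discovery`
    expectations.
    """
    rng = np.random.default_rng(seed)
    rates = dict(DEFAULT_BASELINE_RATES if baseline_rates is None else baseline_rates)
    risk = dict(risk_genes)
    out = {"gene_id": [f"G{i:05d}" for i in range(n_genes)]}
    for cls in CLASSES:
        lam = np.full(n_genes, float(rates.get(cls, 0.0)))
        if rate_dispersion > 0:
            shape = 1.0 / rate_dispersion**2
            lam = lam * rng.gamma(shape, 1.0 / shape, size=n_genes)
        case_lam = lam.copy()
        if cls == "class_I":
            for g, or_ in risk.items():
                case_lam[g] = lam[g] * or_
        ctl_lam = lam.copy()
        if cls == "synonymous":
            ctl_lam = ctl_lam * synonymous_perturbation
        out[f"case_{cls}"] = rng.binomial(2 * n_case, np.clip(case_lam / 2, 0, 1))
        out[f"control_{cls}"] = rng.binomial(2 * n_control, np.clip(ctl_lam / 2, 0, 1))
    return pd.DataFrame(out)


QC_RULES = (
    "vqsr",
    "low_dp",
    "homref_low_gq",
    "het_allele_balance",
    "variant_callrate",
    "sample_callrate",
)


def simulate_genotype_calls(
    n_samples: int,
    n_variants: int,
    qc_failure_rates: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotype-call table with planted, labeled QC violations.

    Clean calls are high-depth balanced heterozygotes or confident
    hom-refs that pass every filter. ``qc_failure_rates`` maps a rule
    name (see ``QC_RULES``) to the fraction of calls (or of
    variants/samples for the call-rate rules) planted to violate it.
    The ``planted`` column records the rule, empty for clean calls, so
    tests can compare removals against ground truth exactly.
    """
    rates = dict(qc_failure_rates or {})
    unknown = set(rates) - set(QC_RULES)
    if unknown:
        raise ValueError(f"unknown QC rule(s): {sorted(unknown)}")
    for rule, r in rates.items():
        if not 0 <= r <= 1:
            raise ValueError(f"failure rate for {rule} outside [0, 1]")
    rng = np.random.default_rng(seed)

    samples = [f"S{i:04d}" for i in range(n_samples)]
    variants = [f"v{j:05d}" for j in range(n_variants)]
    n_calls = n_samples * n_variants
    sample_col = np.repeat(samples, n_variants)
    variant_col = np.tile(variants, n_samples)

    genotype = np.where(rng.random(n_calls) < 0.5, "het", "hom_ref")
    dp = rng.integers(40, 120, n_calls)
    gq = np.full(n_calls, 99)
    pl_homref = np.full(n_calls, 250)
    vqsr = np.ones(n_calls, dtype=bool)
    planted = np.array([""] * n_calls, dtype=object)

    is_het = genotype == "het"
    ad_alt = np.where(is_het, (dp * 0.5).astype(int), 0)
    ad_ref = dp - ad_alt

    free = np.ones(n_calls, dtype=bool)  # calls not yet planted with a violation

    def plant(rule: str, mask_candidates: np.ndarray, rate: float) -> np.ndarray:
        cand = np.flatnonzero(mask_candidates & free)
        k = int(round(rate * n_calls))
        pick = rng.choice(cand, size=min(k, cand.size), replace=False)
        free[pick] = False
        planted[pick] = rule
        return pick

    if rates.get("vqsr", 0) > 0:
        pick = plant("vqsr", np.ones(n_calls, dtype=bool), rates["vqsr"])
        vqsr[pick] = False
    if rates.get("low_dp", 0) > 0:
        pick = plant("low_dp", np.ones(n_calls, dtype=bool), rates["low_dp"])
        dp[pick] = rng.integers(0, 10, pick.size)
        ad_alt[pick] = np.minimum(ad_alt[pick], dp[pick])
        ad_ref[pick] = dp[pick] - ad_alt[pick]
    if rates.get("homref_low_gq", 0) > 0:
        pick = plant("homref_low_gq", genotype == "hom_ref", rates["homref_low_gq"])
        gq[pick] = rng.integers(0, 25, pick.size)
    if rates.get("het_allele_balance", 0) > 0:
        # extreme skew: every read on the alternate allele, so the
        # two-tailed binomial p is 2 * 0.5^dp, far below 1e-9 at dp >= 40
        pick = plant("het_allele_balance", is_het, rates["het_allele_balance"])
        ad_alt[pick] = dp[pick]
        ad_ref[pick] = 0

    df = pd.DataFrame(
        {
            "sample_id": sample_col,
            "variant_id": variant_col,
            "genotype": genotype,
            "dp": dp,
            "gq": gq,
            "pl_homref": pl_homref,
            "ad_ref": ad_ref,
            "ad_alt": ad_alt,
            "vqsr_pass": vqsr,
            "planted": planted,
        }
    )

    # call-rate violations are planted by blanking genotypes to missing
    if rates.get("variant_callrate", 0) > 0:
        k = int(round(rates["variant_callrate"] * n_variants))
        bad_variants = rng.choice(variants, size=k, replace=False)
        for v in bad_variants:
            rows = df.index[df["variant_id"] == v]
            n_missing = int(np.ceil(0.15 * len(rows)))  # call rate ~0.85 < 0.90
            drop = rng.choice(rows, size=n_missing, replace=False)
            df.loc[drop, "genotype"] = "missing"
            df.loc[df["variant_id"] == v, "planted"] = "variant_callrate"
    if rates.get("sample_callrate", 0) > 0:
        k = int(round(rates["sample_callrate"] * n_samples))
        bad_samples = rng.choice(samples, size=k, replace=False)
        for s in bad_samples:
            rows = df.index[(df["sample_id"] == s) & (df["genotype"] != "missing")]
            n_missing = int(np.ceil(0.07 * n_variants))  # call rate ~0.93 < 0.95
            drop = rng.choice(rows, size=min(n_missing, len(rows)), replace=False)
            df.loc[drop, "genotype"] = "missing"
            df.loc[df["sample_id"] == s, "planted"] = np.where(
                df.loc[df["sample_id"] == s, "planted"] == "",
                "sample_callrate",
                df.loc[df["sample_id"] == s, "planted"],
            )
    return df


def simulate_clinical_iq(
    n: int = 962,
    beta: float = -2.25,
    exposure_rate: float = 0.3,
    resid_sd: float = 15.0,
    iq_mean: float = 105.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical-sample IQ table: ultra-rare deleterious-variant count
    (Poisson) and IQ = mean + beta x count + noise, plus the clinical
    covariate columns."""
    rng = np.random.default_rng(seed)
    count = rng.poisson(exposure_rate, n)
    df = pd.DataFrame(
        {
            "individual_id": [f"clin_{i:05d}" for i in range(n)],
            "ultra_rare_class_I": count,
            "sex": np.where(rng.random(n) < 0.6, "male", "female"),
            "n_synonymous_ultra_rare": rng.poisson(1.0, n),
            "n_variants_total": rng.poisson(50, n),
        }
    )
    for i in range(1, 11):
        df[f"PC{i}"] = rng.normal(0, 1, n)
    df["iq"] = iq_mean + beta * count + rng.normal(0, resid_sd, n)
    df["sex"] = (df["sex"] == "male").astype(int)
    return df


def attach_outcomes(
    cohort: pd.DataFrame,
    carrier_col: str,
    outcome_or: float = 1.25,
    base_prevalence: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Add binary outcome columns (low education / low SES style) to the
    case subset: P(outcome) follows a logistic model with log(outcome_or)
    per carrier status."""
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    carrier = (out[carrier_col] > 0).astype(int)
    alpha = np.log(base_prevalence / (1 - base_prevalence))
    p = 1 / (1 + np.exp(-(alpha + np.log(outcome_or) * carrier)))
    out["outcome_low"] = (rng.random(len(out)) < p).astype(int)
    return out
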