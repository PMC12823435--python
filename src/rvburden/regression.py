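"""Burden regressions on per-individual rare-variant counts.

Category-level and gene-set burden tests model case status (or a binary
outcome) as a logistic function of a per-individual qualifying-variant
count, adjusted for the study covariates (sex, birth year, principal
components, total and synonymous variant counts, coverage metrics and
sequencing wave). Effects are reported as odds ratios per unit count
with Wald 95% confidence intervals. Tiny gene sets in small comorbid
subgroups routinely separate, so a bias-reduced (Firth-type penalized)
fit is used as a fallback and flagged in the result.

Also here: the carrier-based socioeconomic outcome association (with a
Fisher cross-check on the unadjusted 2x2), the linear IQ model on
ultra-rare deleterious-variant counts, and the joint analysis of rare
class I carriers with a common-variant polygenic score (PGS) binned
into pentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .annotation import Zone
from .discovery import gene_fisher

__all__ = [
    "BurdenResult",
    "per_person_count",
    "burden_logistic",
    "firth_logistic",
    "geneset_comorbidity_scan",
    "outcome_association",
    "iq_linear",
    "pentile_bins",
    "joint_pgs_analysis",
    "STANDARD_COVARIATES",
]

# Cohort covariate scheme used throughout the population-cohort models.
STANDARD_COVARIATES = (
    ["birth_year", "sex"]
    + [f"PC{i}" for i in range(1, 11)]
    + ["n_variants_total", "n_synonymous_rare", "pct_target_20x", "mean_depth"]
)

Z95 = stats.norm.ppf(0.975)


@dataclass
class BurdenResult:
    """One fitted exposure effect (logistic or linear)."""

    beta: float
    se: float
    p_value: float
    n_used: int
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    method: str = "logistic"
    notes: str = ""
    extra: dict = field(default_factory=dict)


def per_person_count(
    counts: pd.DataFrame,
    individuals: pd.DataFrame,
    gene_set: Iterable[str],
    variant_class: str,
    known_genes: Iterable[str] | None = None,
) -> pd.Series:
    """Per-individual number of qualifying rare alleles in a gene set.

    ``counts`` is long-format (individual_id, gene_id, vclass, count[,
    zone]); ``individuals`` must carry ``individual_id`` and ``sex``
    ("male"/"female"). Male allele counts in X non-PAR genes are doubled
    to account for hemizygosity. Genes in ``gene_set`` absent from
    ``known_genes`` (when given) are warned about and ignored.
    """
    gene_set = set(gene_set)
    if known_genes is not None:
        unknown = gene_set - set(known_genes)
        if unknown:
            import warnings

            warnings.warn(f"{len(unknown)} gene(s) in set not in the count table; ignored")
            gene_set -= unknown
    sub = counts[(counts["vclass"] == variant_class) & counts["gene_id"].isin(gene_set)].copy()
    weights = np.ones(len(sub))
    if "zone" in sub.columns and len(sub):
        sex = individuals.set_index("individual_id")["sex"]
        is_male = sub["individual_id"].map(sex).eq("male").to_numpy()
        nonpar = (sub["zone"] == Zone.X_NONPAR.value).to_numpy()
        weights = np.where(is_male & nonpar, 2.0, 1.0)
    sub["weighted"] = sub["count"].to_numpy() * weights
    per = sub.groupby("individual_id")["weighted"].sum()
    out = per.reindex(individuals["individual_id"], fill_value=0.0)
    out.index = individuals["individual_id"]
    return out.astype(float)


def _design(
    exposure: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(exposure, dtype=float), np.asarray(exposure, dtype=float)]
    names = ["const", "exposure"]
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.astype(float)
        # drop zero-variance then collinear columns to keep the fit full rank
        cov = cov.loc[:, cov.std(ddof=0) > 0]
        X = np.column_stack(cols + [cov.to_numpy()])
        keep = []
        base_rank = np.linalg.matrix_rank(np.column_stack(cols))
        cur = np.column_stack(cols)
        for j, name in enumerate(cov.columns):
            cand = np.column_stack([cur, cov.iloc[:, j].to_numpy()])
            if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(cur):
                cur = cand
                keep.append(name)
        return cur, names + keep
    return np.column_stack(cols), names


def firth_logistic(
    y: np.ndarray, X: np.ndarray, max_iter: int = 200, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Bias-reduced logistic regression (Jeffreys-prior penalized score).

    Newton iterations on the modified score
    ``U*(b) = X' (y - p + h (1/2 - p))`` with h the hat-matrix diagonal;
    finite estimates exist under complete separation. Returns
    ``(beta, covariance)``.
    """
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1 / (1 + np.exp(-eta))
        w = p * (1 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    p = 1 / (1 + np.exp(-eta))
    w = p * (1 - p)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, cov


def burden_logistic(
    outcome: Sequence[int],
    exposure: Sequence[float],
    covariates: pd.DataFrame | None = None,
) -> BurdenResult:
    """Logistic burden model: outcome ~ exposure + covariates.

    Reports the exposure OR per unit count with Wald 95% CI and
    two-sided p. On (quasi-)separation or non-convergence of the ML fit,
    falls back to the Firth-type bias-reduced fit (``method='firth'``).
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if y.size != x.size:
        raise ValueError("outcome and exposure lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    if np.std(x) == 0:
        raise ValueError("exposure has no variance")
    X, names = _design(x, covariates)

    method = "logistic"
    notes = ""
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = fit.params
        cov = fit.cov_params()
        converged = bool(fit.mle_retvals.get("converged", True))
        se1 = np.sqrt(np.diag(cov))[1]
        if not converged or not np.isfinite(se1) or se1 > 50 or abs(beta[1]) > 30:
            raise sm.tools.sm_exceptions.PerfectSeparationError("unstable ML fit")
    except Exception:
        beta, cov = firth_logistic(y, X)
        method = "firth"
        notes = "bias-reduced fit after detected separation/non-convergence"

    b, se = float(beta[1]), float(np.sqrt(np.diag(cov))[1])
    p = 2 * stats.norm.sf(abs(b / se)) if se > 0 else float("nan")
    return BurdenResult(
        beta=b,
        se=se,
        p_value=float(p),
        n_used=int(y.size),
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - Z95 * se)),
        ci_high=float(np.exp(b + Z95 * se)),
        method=method,
        notes=notes,
        extra={"terms": names},
    )


def geneset_comorbidity_scan(
    cohort: pd.DataFrame,
    gene_sets: Sequence[str],
    classes: Sequence[str],
    contrasts: Sequence[tuple[str, pd.Series, pd.Series]],
    covariate_cols: Sequence[str] = tuple(STANDARD_COVARIATES),
    family_alpha: float = 0.05 / 7,
    min_subgroup: int = 50,
) -> pd.DataFrame:
    """Gene-set burden scan across comorbid subgroups.

    One logistic fit per (gene set, variant class, contrast); the
    exposure is the ``{set}_{class}`` count column, the outcome is
    membership in group A vs group B of the contrast. Contrasts are
    ``(label, mask_A, mask_B)`` boolean Series over ``cohort``.
    Subgroups below ``min_subgroup`` are skipped with a status row.
    Significance is flagged at the per-family Bonferroni level
    ``family_alpha`` (0.05/7 for the seven disorder gene sets).
    """
    rows = []
    for label, mask_a, mask_b in contrasts:
        sub = cohort[mask_a | mask_b]
        y = mask_a[mask_a | mask_b].astype(int).to_numpy()
        for gs in gene_sets:
            for cls in classes:
                col = f"{gs}_{cls}"
                rec = {"gene_set": gs, "vclass": cls, "contrast": label}
                if int(y.sum()) < min_subgroup or int((1 - y).sum()) < min_subgroup:
                    rec.update(status="skipped_small_subgroup", p_value=np.nan)
                    rows.append(rec)
                    continue
                if col not in sub.columns:
                    raise KeyError(f"missing count column {col}")
                cov = sub[[c for c in covariate_cols if c in sub.columns]]
                try:
                    res = burden_logistic(y, sub[col].to_numpy(), cov)
                except ValueError as err:
                    rec.update(status=f"failed: {err}", p_value=np.nan)
                    rows.append(rec)
                    continue
                rec.update(
                    status="ok",
                    beta=res.beta,
                    se=res.se,
                    odds_ratio=res.odds_ratio,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    p_value=res.p_value,
                    method=res.method,
                    n_used=res.n_used,
                    significant=res.p_value < family_alpha,
                )
                rows.append(rec)
    return pd.DataFrame(rows)


def outcome_association(
    cohort: pd.DataFrame,
    carrier_col: str,
    outcome_col: str,
    covariate_cols: Sequence[str] = tuple(STANDARD_COVARIATES),
) -> tuple[BurdenResult, dict]:
    """Carrier (>= 1 qualifying variant) association with a binary
    outcome: adjusted logistic fit plus a two-tailed Fisher's exact test
    on the unadjusted 2x2 as a secondary statistic."""
    sub = cohort.dropna(subset=[outcome_col])
    y = sub[outcome_col].astype(int).to_numpy()
    carrier = (sub[carrier_col] > 0).astype(int).to_numpy()
    cov = sub[[c for c in covariate_cols if c in sub.columns]]
    logit = burden_logistic(y, carrier, cov)
    res = gene_fisher(
        int(carrier[y == 1].sum()),
        int(carrier[y == 0].sum()),
        int((y == 1).sum()),
        int((y == 0).sum()),
        unit="carriers",
    )
    fisher = {"odds_ratio": res.odds_ratio, "p_value": res.p_value, "table": res.table}
    return logit, fisher


def iq_linear(
    cohort: pd.DataFrame,
    exposure_col: str,
    iq_col: str = "iq",
    covariate_cols: Sequence[str] = ("sex",)
    + tuple(f"PC{i}" for i in range(1, 11))
    + ("n_synonymous_ultra_rare", "n_variants_total"),
) -> BurdenResult:
    """OLS of IQ on the ultra-rare deleterious-variant count (clinical
    covariate scheme: sex, PCs, ultra-rare synonymous count, total
    variants). Effect is IQ points per additional variant."""
    sub = cohort.dropna(subset=[iq_col])
    x = sub[exposure_col].astype(float).to_numpy()
    if np.std(x) == 0:
        raise ValueError("exposure has no variance")
    cov = sub[[c for c in covariate_cols if c in sub.columns]]
    X, names = _design(x, cov)
    fit = sm.OLS(sub[iq_col].astype(float).to_numpy(), X).fit()
    b, se = float(fit.params[1]), float(fit.bse[1])
    return BurdenResult(
        beta=b,
        se=se,
        p_value=float(fit.pvalues[1]),
        n_used=int(len(sub)),
        ci_low=b - Z95 * se,
        ci_high=b + Z95 * se,
        method="ols",
        extra={"terms": names},
    )


def pentile_bins(pgs: pd.Series) -> pd.Series:
    """Five equal-count PGS bins (1..5) with stable tie-breaking.

    Individuals are ordered by (PGS value, index id) with a stable sort
    and split into five consecutive blocks whose sizes differ by at most
    one, so the assignment is invariant to input order.
    """
    order = pgs.reset_index(drop=True)
    idx = np.lexsort((pgs.index.astype(str), order.to_numpy()))
    bins = np.empty(len(pgs), dtype=int)
    for b, chunk in enumerate(np.array_split(np.arange(len(pgs)), 5), start=1):
        bins[idx[chunk]] = b
    return pd.Series(bins, index=pgs.index, name="pgs_pentile")


def joint_pgs_analysis(
    cohort: pd.DataFrame,
    pgs_col: str = "pgs",
    carrier_col: str = "class_I_constrained",
    status_col: str = "status",
    covariate_cols: Sequence[str] = tuple(STANDARD_COVARIATES),
) -> pd.DataFrame:
    """Joint rare-variant x polygenic-score stratified risk model.

    The PGS is cut into pentiles on the modeled individuals; crossing
    the five bins with carrier status (>= 1 class I variant in
    constrained genes) gives ten strata. Case status is regressed on
    nine stratum dummies (reference: pentile 1, non-carrier, OR = 1 by
    construction) plus the standard covariates. Returns one row per
    stratum with OR and Wald CI; empty strata are flagged and dropped
    from the design.
    """
    sub = cohort.dropna(subset=[pgs_col]).copy()
    sub["pentile"] = pentile_bins(sub[pgs_col])
    sub["carrier"] = (sub[carrier_col] > 0).astype(int)
    y = sub[status_col].astype(int).to_numpy()

    strata = [(b, c) for c in (0, 1) for b in range(1, 6)]
    dummy_cols = []
    dummies = {}
    for b, c in strata:
        if (b, c) == (1, 0):
            continue  # reference stratum
        name = f"bin{b}_carrier{c}"
        dummies[name] = ((sub["pentile"] == b) & (sub["carrier"] == c)).astype(float)
        dummy_cols.append(name)
    D = pd.DataFrame(dummies, index=sub.index)
    empty = [c for c in dummy_cols if D[c].sum() == 0]
    D = D.drop(columns=empty)

    cov = sub[[c for c in covariate_cols if c in sub.columns]].astype(float)
    cov = cov.loc[:, cov.std(ddof=0) > 0]
    X = sm.add_constant(pd.concat([D, cov], axis=1).to_numpy())
    names = ["const"] + list(D.columns) + list(cov.columns)
    with np.errstate(all="ignore"):
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)

    rows = [
        {
            "pentile": 1,
            "carrier": 0,
            "odds_ratio": 1.0,
            "ci_low": 1.0,
            "ci_high": 1.0,
            "p_value": np.nan,
            "n": int(((sub["pentile"] == 1) & (sub["carrier"] == 0)).sum()),
            "reference": True,
            "status": "reference",
        }
    ]
    se_all = np.sqrt(np.diag(fit.cov_params()))
    for b, c in strata:
        if (b, c) == (1, 0):
            continue
        name = f"bin{b}_carrier{c}"
        n_stratum = int(((sub["pentile"] == b) & (sub["carrier"] == c)).sum())
        if name in empty:
            rows.append(
                {"pentile": b, "carrier": c, "odds_ratio": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p_value": np.nan, "n": n_stratum,
                 "reference": False, "status": "empty_stratum_dropped"}
            )
            continue
        j = names.index(name)
        beta, se = float(fit.params[j]), float(se_all[j])
        rows.append(
            {
                "pentile": b,
                "carrier": c,
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - Z95 * se)),
                "ci_high": float(np.exp(beta + Z95 * se)),
                "p_value": float(2 * stats.norm.sf(abs(beta / se))),
                "n": n_stratum,
                "reference": False,
                "status": "ok",
            }
        )
    return pd.DataFrame(rows)
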