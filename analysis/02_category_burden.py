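#!/usr/bin/env python
"""Category-level burden of rare variant classes in cases vs controls.

Logistic regression of case status on the per-person count of each
variant class (class I, class II, synonymous), in all genes and in
constrained genes, with the standard covariates. The planted truth is
an OR of 1.35 per class-I allele in constrained genes and no synonymous
effect, so the table should show class-I enrichment concentrated in the
constrained set and a null synonymous row.
"""

from pathlib import Path

import pandas as pd

from rvburden.io import read_dataset, write_table
from rvburden.regression import STANDARD_COVARIATES, burden_logistic

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    ds = read_dataset(ROOT / "data")
    coh = ds.cohort.copy()
    coh["sex"] = (coh["sex"] == "male").astype(int)
    cov_cols = [c for c in STANDARD_COVARIATES if c in coh.columns] + [
        c for c in coh.columns if c.startswith("wave_")
    ]

    # per-person totals per class over all genes
    for cls in ("class_I", "class_II", "synonymous"):
        per = ds.counts[ds.counts.vclass == cls].groupby("individual_id")["count"].sum()
        coh[f"all_{cls}"] = coh["individual_id"].map(per).fillna(0).astype(int)

    rows = []
    for gene_set in ("all", "constrained"):
        for cls in ("class_I", "class_II", "synonymous"):
            col = f"{gene_set}_{cls}"
            cov = coh[cov_cols].copy()
            if cls == "synonymous":
                cov = cov.drop(columns=["n_synonymous_rare"])  # outcome-as-covariate
            res = burden_logistic(coh["status"].astype(int), coh[col], cov)
            rows.append(
                {"gene_set": gene_set, "vclass": cls, "odds_ratio": res.odds_ratio,
                 "ci_low": res.ci_low, "ci_high": res.ci_high, "p_value": res.p_value,
                 "n_used": res.n_used, "method": res.method}
            )
    table = pd.DataFrame(rows)
    write_table(table, ROOT / "category_burden.tsv", ds.truth, ds.truth.get("seed"))
    print(table.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    con = table[(table.gene_set == "constrained") & (table.vclass == "class_I")].iloc[0]
    print(f"\nconstrained-gene class-I burden: OR {con.odds_ratio:.2f} "
          f"[{con.ci_low:.2f}, {con.ci_high:.2f}]")
    print("(planted per-allele OR 1.35; the ID-linked extra load in the NDD subset of "
          "constrained genes pushes the marginal estimate above the per-allele tilt)")
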