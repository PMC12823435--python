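#!/usr/bin/env python
"""Gene-set burden across comorbid case subgroups.

Compares the class-I / class-II / synonymous load between cases with
and without each comorbidity (ID first; other comorbidity contrasts
exclude ID cases) in the constrained-gene stratum and the
comorbidity-linked gene set. The generator plants NDD-set enrichment
only in cases with ID, so the scan should flag that contrast and
nothing else; synonymous rows are the sanity check.
"""

from pathlib import Path

from rvburden.io import read_dataset, write_table
from rvburden.regression import geneset_comorbidity_scan

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    ds = read_dataset(ROOT / "data")
    coh = ds.cohort.copy()
    coh["sex"] = (coh["sex"] == "male").astype(int)
    cases = coh.status == 1
    contrasts = []
    for com in ("ID", "ASD", "SCZ", "SUD", "DBD", "multimorbidity"):
        a, b = cases & (coh[com] == 1), cases & (coh[com] == 0)
        if com != "ID":
            a, b = a & (coh.ID == 0), b & (coh.ID == 0)
        contrasts.append((f"with_{com}_vs_without", a, b))
    table = geneset_comorbidity_scan(
        coh, ["constrained", "NDD_set"], ["class_I", "class_II", "synonymous"], contrasts
    )
    write_table(table, ROOT / "comorbidity_scan.tsv", ds.truth, ds.truth.get("seed"))
    ok = table[table.status == "ok"]
    hits = ok[ok.significant.fillna(False)]
    print(f"{len(ok)} fits, {len(hits)} significant at 0.05/7:")
    cols = ["gene_set", "vclass", "contrast", "odds_ratio", "p_value"]
    print(hits[cols].to_string(index=False, float_format=lambda x: f"{x:.3g}")
          if len(hits) else "  none")
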