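"""Tabular I/O, run configuration and output provenance.

All tables are TSV with required named headers; a VCF front-end (SnpEff
style ``ANN`` consequence field plus an ``MPC`` INFO tag) converts to
the variant TSV on ingestion. Output tables carry a header comment line
with the tool version, a hash of the configuration and the seed, so a
result file can always be traced to the run that produced it. Readers
validate required columns and numeric fields row by row, reporting the
offending line number rather than silently coercing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation import Consequence, VariantRecord, Zone
from .simulate import SimulationConfig, SyntheticDataset

__all__ = [
    "RunConfig",
    "config_hash",
    "write_table",
    "read_table",
    "read_variants_tsv",
    "variants_from_vcf",
    "write_dataset",
    "read_dataset",
    "write_run_metadata",
]


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    autosomal_threshold: int = 5
    x_nonpar_threshold: int | None = None  # None -> derive from sample counts
    n_males: int | None = None
    n_females: int | None = None
    burden_unit: str = "alleles"  # alleles | carriers (autosomal discovery)
    meta_weights: str | tuple[float, float] = "auto"
    x_meta_weight: float = 0.55
    min_coverage_fraction: float = 0.80
    subgroup_min_size: int = 50
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.autosomal_threshold <= 0:
            raise ValueError("autosomal_threshold must be positive")
        if self.burden_unit not in ("alleles", "carriers"):
            raise ValueError("burden_unit must be 'alleles' or 'carriers'")
        if not 0 < self.min_coverage_fraction <= 1:
            raise ValueError("min_coverage_fraction must be in (0, 1]")
        if self.meta_weights != "auto":
            w1, w2 = self.meta_weights
            if w1 <= 0 or w2 <= 0:
                raise ValueError("meta weights must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(data.get("meta_weights"), list):
            data["meta_weights"] = tuple(data["meta_weights"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["meta_weights"], tuple):
            d["meta_weights"] = list(d["meta_weights"])
        return d


def config_hash(config: Mapping | RunConfig | SimulationConfig) -> str:
    """Short stable hash of a configuration mapping."""
    if hasattr(config, "to_dict"):
        config = config.to_dict()
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_line(cfg_hash: str, seed: int | None) -> str:
    seed_part = "" if seed is None else f" seed={seed}"
    return f"# rvburden v{__version__} config={cfg_hash}{seed_part}"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: Mapping | RunConfig | SimulationConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write a TSV with a provenance header comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config) if config is not None else "none"
    with open(path, "w") as fh:
        fh.write(_provenance_line(cfg_hash, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(
    path: str | Path,
    required: Sequence[str] = (),
    numeric: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a TSV (skipping ``#`` provenance comments), checking that
    required columns exist and numeric columns parse; malformed rows are
    reported with their 1-based line number."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    header_offset = 2  # provenance line + header line
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        header_offset = 1
    for col in numeric:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            line = int(bad[0]) + header_offset + 1
            raise ValueError(
                f"{path}: line {line}: cannot parse {col}={df.loc[bad[0], col]!r} as a number"
            )
        df[col] = parsed
    return df


# ---------------------------------------------------------------------------
# variants


def read_variants_tsv(path: str | Path, dataset_labels: Sequence[str] | None = None) -> list[VariantRecord]:
    """Annotated variant TSV -> :class:`VariantRecord` list.

    Expected columns: variant_id, chrom, pos, ref, alt, gene_id,
    consequence, lof_flag, mpc, zone and one ``ac_<label>`` column per
    dataset.
    """
    df = read_table(
        path,
        required=["variant_id", "chrom", "pos", "ref", "alt", "gene_id", "consequence"],
        numeric=["pos", "mpc"],
    )
    ac_cols = [c for c in df.columns if c.startswith("ac_")]
    if dataset_labels is not None:
        want = {f"ac_{lab}" for lab in dataset_labels}
        missing = want - set(ac_cols)
        if missing:
            raise ValueError(f"{path}: missing allele-count column(s) {sorted(missing)}")
        ac_cols = sorted(want)
    records = []
    for i, row in df.iterrows():
        mpc = row.get("mpc")
        records.append(
            VariantRecord(
                variant_id=row["variant_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene_id=row["gene_id"],
                consequence=Consequence(row["consequence"]),
                lof_flag=str(row.get("lof_flag", "False")).lower() in ("true", "1"),
                mpc=None if pd.isna(mpc) else float(mpc),
                zone=Zone(row.get("zone", "autosome") if pd.notna(row.get("zone")) else "autosome"),
                allele_counts={c[3:]: int(row[c]) for c in ac_cols},
            )
        )
    return records


_ANN_CONSEQUENCE_MAP = {
    "stop_gained": Consequence.STOP_GAINED,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "splice_acceptor_variant": Consequence.SPLICE_SITE,
    "splice_donor_variant": Consequence.SPLICE_SITE,
    "missense_variant": Consequence.MISSENSE,
    "synonymous_variant": Consequence.SYNONYMOUS,
}


def variants_from_vcf(path: str | Path, dataset_label: str = "cohort") -> list[VariantRecord]:
    """Optional VCF front-end: parses a SnpEff-style ``ANN`` INFO field
    (effect and gene), an ``MPC`` tag and ``LOF`` flag. Allele counts
    come from the ``AC`` field under ``dataset_label``."""
    from cyvcf2 import VCF  # deferred: VCF input is optional

    records = []
    for var in VCF(str(path)):
        ann = var.INFO.get("ANN")
        if ann is None:
            continue
        first = ann.split(",")[0].split("|")
        effect = first[1] if len(first) > 1 else "other"
        gene = first[3] if len(first) > 3 else ""
        cons = _ANN_CONSEQUENCE_MAP.get(effect.split("&")[0], Consequence.OTHER)
        mpc = var.INFO.get("MPC")
        ac = var.INFO.get("AC")
        if isinstance(ac, tuple):
            ac = ac[0]
        records.append(
            VariantRecord(
                variant_id=var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}",
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0],
                gene_id=gene,
                consequence=cons,
                lof_flag=var.INFO.get("LOF") is not None,
                mpc=float(mpc) if mpc is not None else None,
                zone=Zone.AUTOSOME,
                allele_counts={dataset_label: int(ac or 0)},
            )
        )
    return records


# ---------------------------------------------------------------------------
# synthetic dataset round-trip


def write_dataset(ds: SyntheticDataset, outdir: str | Path, seed: int | None = None) -> Path:
    """Serialize a synthetic dataset: phenotype TSV, long count TSV,
    gene/external/coverage TSVs and a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = ds.truth
    seed = cfg.get("seed") if seed is None else seed
    write_table(ds.cohort, outdir / "cohort.tsv", cfg, seed)
    write_table(ds.counts, outdir / "counts.tsv", cfg, seed)
    write_table(ds.genes, outdir / "genes.tsv", cfg, seed)
    write_table(ds.external_counts, outdir / "external_counts.tsv", cfg, seed)
    write_table(ds.coverage, outdir / "coverage.tsv", cfg, seed)
    sidecar = {"truth": cfg, "n_external": ds.n_external, "version": __version__}
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return outdir


def read_dataset(outdir: str | Path) -> SyntheticDataset:
    """Inverse of :func:`write_dataset`; counts round-trip exactly."""
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "truth.json").read_text())
    cohort = read_table(outdir / "cohort.tsv", required=["individual_id", "status"])
    num_cols = [c for c in cohort.columns if c not in ("individual_id", "sex")]
    for c in num_cols:
        cohort[c] = pd.to_numeric(cohort[c])
    counts = read_table(
        outdir / "counts.tsv",
        required=["individual_id", "gene_id", "vclass", "count"],
        numeric=["count"],
    )
    counts["count"] = counts["count"].astype(int)
    genes = read_table(outdir / "genes.tsv", required=["gene_id", "pli"], numeric=["pli"])
    genes["constrained"] = genes["constrained"].astype(str).str.lower().isin(("true", "1"))
    ext = read_table(outdir / "external_counts.tsv", required=["gene_id"])
    for c in ext.columns:
        if c != "gene_id":
            ext[c] = pd.to_numeric(ext[c]).astype(int)
    coverage = read_table(
        outdir / "coverage.tsv",
        required=["gene_id", "coverage_internal", "coverage_external"],
        numeric=["coverage_internal", "coverage_external"],
    )
    return SyntheticDataset(
        cohort=cohort,
        counts=counts,
        genes=genes,
        external_counts=ext,
        n_external=int(sidecar["n_external"]),
        coverage=coverage,
        truth=sidecar["truth"],
    )


def write_run_metadata(path: str | Path, config, seed: int | None, **tallies) -> Path:
    """Run-metadata JSON: exact config, provenance and filter tallies."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "version": __version__,
        "config": config.to_dict() if hasattr(config, "to_dict") else config,
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
    }
    payload.update(tallies)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
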