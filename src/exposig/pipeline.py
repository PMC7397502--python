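"""End-to-end orchestration: VCFs in, catalogues/signatures/statistics out.

Thin composition layer over the library modules; every step is also
available programmatically.  Outputs are deterministic given the same
config and inputs (timestamps live only in the log), and every matrix
or profile written uses the canonical channel ordering so any output
re-ingests cleanly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .catalog import MutationCatalog, build_catalog, class_anova, class_percentages
from .classify import classify_records, merge_adjacent_snvs
from .compare import fit_exposures, rank_matches
from .derive import derive_exposure_signature
from .io import (
    load_reference,
    read_gene_models,
    read_signature_catalog,
    read_vcf,
)
from .selection import (
    enrichment_table,
    count_gene_mutations,
    expression_rate_regression,
    gene_enrichment_test,
)

log = logging.getLogger("exposig")

SCHEMES = ("SBS96", "DBS78", "ID")


@dataclass
class RunConfig:
    """Validated inputs and parameters for a pipeline run."""

    reference: Path
    samplesheet: Path  # TSV: sample, vcf (relative to the sheet), group
    signature_catalog: Optional[Path] = None  # for `signature` comparisons
    catalog_subset: Optional[list[str]] = None  # restrict to named signatures
    genes_bed: Optional[Path] = None
    expression: Optional[Path] = None
    schemes: tuple[str, ...] = SCHEMES
    derive_mode: str = "mean-subtract"
    merge_adjacent: bool = True
    keep_all_filters: bool = False
    n_bins: int = 10
    effective_genome_bp: Optional[int] = None  # default: reference length
    enrichment_model: str = "poisson"
    fdr_alpha: float = 0.05
    selection_group: str = "exposed"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("reference", "samplesheet", "signature_catalog", "genes_bed", "expression"):
            if raw.get(key) is not None:
                p = Path(raw[key])
                if not p.is_absolute():
                    p = path.parent / p
                raw[key] = p
        if "schemes" in raw:
            raw["schemes"] = tuple(raw["schemes"])
        return cls(**raw)

    def validate(self, need_groups: bool = False) -> None:
        for key in ("reference", "samplesheet"):
            p = getattr(self, key)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{key} not found: {p}")
        for key in ("signature_catalog", "genes_bed", "expression"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} not found: {p}")
        if need_groups:
            sheet = read_samplesheet(self.samplesheet)
            groups = set(sheet["group"])
            if not {"control", "exposed"} <= groups:
                raise ValueError(
                    "signature derivation needs both 'control' and 'exposed' "
                    f"samples; sample sheet has {sorted(groups)}"
                )

    def hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in dataclasses.asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_samplesheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "vcf", "group"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    bad = set(sheet["group"]) - {"control", "exposed"}
    if bad:
        raise ValueError(f"unknown group label(s) {sorted(bad)}")
    if sheet["sample"].duplicated().any():
        raise ValueError("duplicated sample names in sample sheet")
    return sheet


@dataclass
class CatalogBundle:
    """Catalogues for all requested schemes plus record accounting."""

    catalogs: dict[str, MutationCatalog]
    groups: dict[str, str]
    n_records: dict[str, int]
    n_flagged_runs: int
    genome_bp: int
    skipped_total: int = field(init=False)

    def __post_init__(self) -> None:
        self.skipped_total = sum(
            sum(c.skipped.values()) for c in self.catalogs.values()
        )


def build_catalogs(config: RunConfig) -> CatalogBundle:
    """Read every sample's VCF and build catalogues for each scheme."""
    config.validate()
    genome = load_reference(config.reference)
    sheet = read_samplesheet(config.samplesheet)
    sheet_dir = Path(config.samplesheet).parent
    all_records = []
    n_records = {}
    for row in sheet.itertuples():
        vcf_path = Path(row.vcf)
        if not vcf_path.is_absolute():
            vcf_path = sheet_dir / vcf_path
        recs = read_vcf(
            vcf_path, row.sample, genome=genome, keep_all_filters=config.keep_all_filters
        )
        n_records[row.sample] = len(recs)
        all_records.extend(recs)
    n_flagged = 0
    if config.merge_adjacent:
        all_records, flagged = merge_adjacent_snvs(all_records)
        n_flagged = len(flagged)
    sample_order = list(sheet["sample"])
    catalogs = {}
    for scheme_id in config.schemes:
        classified, skipped = classify_records(all_records, genome, scheme_id)
        catalogs[scheme_id] = build_catalog(
            classified, scheme_id, sample_ids=sample_order, skipped=skipped
        )
    return CatalogBundle(
        catalogs=catalogs,
        groups=dict(zip(sheet["sample"], sheet["group"])),
        n_records=n_records,
        n_flagged_runs=n_flagged,
        genome_bp=genome.total_length,
    )


def _provenance(config: RunConfig) -> dict:
    return {"config_hash": config.hash(), "seed": config.seed, "version": __version__}


def run_catalog(config: RunConfig, outdir) -> CatalogBundle:
    """Build and write per-scheme catalogues plus the SBS class summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = build_catalogs(config)
    qc = {
        "records_per_sample": bundle.n_records,
        "skipped_per_scheme": {s: c.skipped for s, c in bundle.catalogs.items()},
        "flagged_multibase_runs": bundle.n_flagged_runs,
        **_provenance(config),
    }
    for scheme_id, cat in bundle.catalogs.items():
        cat.to_tsv(outdir / f"catalog_{scheme_id}.tsv")
    if "SBS96" in bundle.catalogs:
        sbs = bundle.catalogs["SBS96"]
        if (sbs.row_totals() > 0).all() and len(sbs.counts) >= 1:
            summary = class_percentages(sbs)
            summary.percentages.to_csv(
                outdir / "class_percentages.tsv", sep="\t", index_label="sample"
            )
            per_group = {}
            for group in ("control", "exposed"):
                members = [s for s, g in bundle.groups.items() if g == group]
                if len(members) >= 2:
                    gsum = class_percentages(sbs.subset(members))
                    rep = class_anova(gsum)
                    per_group[group] = {
                        "f_stat": rep.f_stat,
                        "p_value": rep.p_value,
                        "mean_pct": {c: float(gsum.mean[c]) for c in gsum.class_labels},
                        "sd_pct": {c: float(gsum.sd[c]) for c in gsum.class_labels},
                    }
                    rep.tukey.to_csv(
                        outdir / f"tukey_{group}.tsv", sep="\t", index=False
                    )
            qc["class_anova"] = per_group
    with open(outdir / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
    return bundle


def run_signature(config: RunConfig, outdir) -> dict:
    """Derive per-scheme exposure profiles; rank and refit against a
    catalogue when one is supplied."""
    config.validate(need_groups=True)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = build_catalogs(config)
    control = [s for s, g in bundle.groups.items() if g == "control"]
    exposed = [s for s, g in bundle.groups.items() if g == "exposed"]
    catalog = (
        read_signature_catalog(config.signature_catalog)
        if config.signature_catalog
        else None
    )
    report: dict = {**_provenance(config), "schemes": {}}
    for scheme_id, cat in bundle.catalogs.items():
        entry: dict = {}
        try:
            profile = derive_exposure_signature(
                cat.subset(exposed),
                cat.subset(control),
                mode=config.derive_mode,
                name=f"{scheme_id}-exposure",
            )
        except ValueError as exc:
            entry["error"] = str(exc)
            report["schemes"][scheme_id] = entry
            log.warning("%s: %s", scheme_id, exc)
            continue
        profile.to_tsv(outdir / f"signature_{scheme_id}.tsv")
        entry["support"] = profile.support
        if catalog is not None and catalog.scheme.scheme_id == scheme_id:
            sim = rank_matches(profile, catalog)
            sim.to_tsv(outdir / f"similarity_{scheme_id}.tsv")
            fit = fit_exposures(profile, catalog, subset=config.catalog_subset)
            fit.to_json(outdir / f"fit_{scheme_id}.json")
            entry["best_match"] = {
                "signature": sim.best_match[0],
                "cosine": sim.best_match[1],
            }
            entry["reconstruction_cosine"] = fit.reconstruction_cosine
        report["schemes"][scheme_id] = entry
    with open(outdir / "signature_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_selection(config: RunConfig, outdir) -> dict:
    """Gene enrichment table and expression-rate regression."""
    config.validate()
    if config.genes_bed is None:
        raise ValueError("selection analysis needs a gene BED (genes_bed)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_reference(config.reference)
    sheet = read_samplesheet(config.samplesheet)
    sheet_dir = Path(config.samplesheet).parent
    mutations = []
    for row in sheet.itertuples():
        if config.selection_group != "all" and row.group != config.selection_group:
            continue
        vcf_path = Path(row.vcf)
        if not vcf_path.is_absolute():
            vcf_path = sheet_dir / vcf_path
        mutations.extend(
            read_vcf(vcf_path, row.sample, genome=genome,
                     keep_all_filters=config.keep_all_filters)
        )
    if not mutations:
        raise ValueError(
            f"no mutations found for selection group {config.selection_group!r}"
        )
    genes = read_gene_models(config.genes_bed, config.expression)
    observed = count_gene_mutations(mutations, genes)
    genome_bp = config.effective_genome_bp or genome.total_length
    results = gene_enrichment_test(
        observed,
        total_mutations=len(mutations),
        footprints={g.name: g.footprint_bp for g in genes},
        effective_genome_bp=genome_bp,
        model=config.enrichment_model,
        alpha=config.fdr_alpha,
    )
    enrichment_table(results).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    report: dict = {
        **_provenance(config),
        "n_mutations": len(mutations),
        "n_genes": len(genes),
        "effective_genome_bp": genome_bp,
        "calls": {
            "overmutated": sorted(r.gene for r in results if r.call == "overmutated"),
            "protected": sorted(r.gene for r in results if r.call == "protected"),
        },
    }
    n_expr = sum(1 for g in genes if g.expression is not None)
    if n_expr >= config.n_bins:
        reg = expression_rate_regression(mutations, genes, n_bins=config.n_bins)
        report["regression"] = reg.to_dict()
    else:
        report["regression"] = {
            "skipped": f"only {n_expr} genes with expression (< {config.n_bins} bins)"
        }
    with open(outdir / "selection.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_all(config: RunConfig, outdir) -> dict:
    outdir = Path(outdir)
    bundle = run_catalog(config, outdir / "catalog")
    out: dict = {"catalog_skipped": bundle.skipped_total}
    groups = set(bundle.groups.values())
    if {"control", "exposed"} <= groups:
        out["signature"] = run_signature(config, outdir / "signature")
    if config.genes_bed is not None:
        out["selection"] = run_selection(config, outdir / "selection")
    return out
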