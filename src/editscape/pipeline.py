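"""End-to-end orchestration: counts -> levels -> filter -> annotate ->
context -> differential -> cis, with every intermediate table persisted
and a JSON summary report whose numbers are re-derivable from the tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as esio
from .annotation import annotate_sites, calls_to_frame, gene_map_from_calls, tabulate_categories
from .cis import cis_scan, effective_gene_lengths, tpm
from .context import (
    UNIFORM_BACKGROUND,
    extract_contexts,
    genome_background,
    position_enrichment,
)
from .core import EditingSite, SiteCountMatrix
from .detection import (
    canonicalize_variant,
    compute_levels,
    filter_high_confidence,
    group_site_accounting,
)
from .differential import differential_scan, pca_editing
from .genome import Genome

log = logging.getLogger("editscape")


@dataclass
class RunConfig:
    """Paths and per-stage parameters for one reproducible run."""

    counts: str
    reference: str
    annotation: str
    known_sites: str
    gene_counts: str
    metadata: str
    out_dir: str
    counts_format: str | None = None  # tsv dir or vcf; None = autodetect
    min_coverage: int = 10
    min_level: float = 0.01
    min_samples: int = 2
    match_known_strand: bool = True
    allow_antisense: bool = False
    detect_min_samples: int = 1
    flank: int = 6
    background: str = "reference"  # or "uniform"
    alpha: float = 0.05
    use_fdr: bool = False
    min_per_group: int = 3
    test: str = "kw"
    p_cutoff: float = 0.05
    cis_scope: str = "significant"  # or "all"
    case_label: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("counts", "reference", "annotation", "known_sites", "gene_counts", "metadata"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        if not 0.0 < self.min_level < 1.0:
            raise ValueError("min_level must lie in (0, 1)")
        if self.flank < 1:
            raise ValueError("flank must be >= 1")
        if self.min_samples < 1 or self.min_coverage < 1:
            raise ValueError("min_samples and min_coverage must be >= 1")
        if self.background not in ("reference", "uniform"):
            raise ValueError("background must be 'reference' or 'uniform'")
        if self.cis_scope not in ("significant", "all"):
            raise ValueError("cis_scope must be 'significant' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _apply_strand_policy(counts: SiteCountMatrix, annotation, allow_antisense: bool):
    """Re-canonicalize against gene strands; antisense A-to-G drops by default."""
    keep, dropped = [], []
    for i, site in enumerate(counts.sites):
        result = canonicalize_variant(
            site.chrom,
            site.pos,
            site.genomic_ref,
            site.genomic_alt,
            strand_hint=site.strand,
            annotation=annotation,
            allow_antisense=allow_antisense,
        )
        if isinstance(result, EditingSite):
            keep.append(i)
        else:
            dropped.append(
                {"chrom": site.chrom, "pos": site.pos, "strand": site.strand, "reason": result.reason}
            )
    return counts.subset(keep), pd.DataFrame(
        dropped, columns=["chrom", "pos", "strand", "reason"]
    )


def run_all(config: RunConfig) -> dict:
    """Execute every stage; persist tables under out_dir; return the report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-inputs"
    try:
        genome = Genome.from_fasta(config.reference)
        annotation = esio.read_gtf(config.annotation)
        known_table = esio.read_known_sites(config.known_sites)
        gene_counts = esio.read_gene_counts(config.gene_counts)
        metadata = esio.read_metadata(config.metadata)
        counts, rejected = esio.read_counts(config.counts, config.counts_format)
        counts, antisense_dropped = _apply_strand_policy(
            counts, annotation, config.allow_antisense
        )
        rejected = pd.concat(
            [rejected, antisense_dropped.assign(ref="", alt="")], ignore_index=True
        )
        rejected.to_csv(out / "rejected_variants.tsv", sep="\t", index=False)

        stage = "editing-levels"
        levels = compute_levels(counts, min_coverage=config.min_coverage)

        stage = "high-confidence-filter"
        known_keys = esio.known_site_keys(known_table, config.match_known_strand)
        retained, decisions = filter_high_confidence(
            levels,
            known_keys,
            min_level=config.min_level,
            min_samples=config.min_samples,
            match_strand=config.match_known_strand,
        )
        decisions.to_csv(out / "filter_decisions.tsv", sep="\t", index=False)
        esio.write_levels(retained, out / "levels.tsv")

        stage = "consequence-annotation"
        calls = annotate_sites(retained.sites, annotation, genome)
        calls_df = calls_to_frame(calls)
        calls_df.to_csv(out / "consequences.tsv", sep="\t", index=False)
        categories = tabulate_categories(calls)
        categories.rename_axis("category").to_frame("count").to_csv(
            out / "category_counts.tsv", sep="\t"
        )
        gene_map = gene_map_from_calls(calls)

        stage = "group-accounting"
        accounting = group_site_accounting(
            retained,
            metadata,
            gene_map=gene_map,
            min_level=config.min_level,
            detect_min_samples=config.detect_min_samples,
        )

        stage = "sequence-context"
        ctx = extract_contexts(retained.sites, genome, flank=config.flank)
        ctx.frequencies().to_csv(out / "context_pfm.tsv", sep="\t", index_label="base")
        background = (
            genome_background(genome) if config.background == "reference" else UNIFORM_BACKGROUND
        )
        enrichment = (
            position_enrichment(ctx, background) if ctx.n_sites else pd.DataFrame()
        )
        enrichment.to_csv(out / "context_enrichment.tsv", sep="\t", index=False)

        stage = "differential-editing"
        diff, diff_skipped = differential_scan(
            retained,
            metadata,
            alpha=config.alpha,
            min_per_group=config.min_per_group,
            use_fdr=config.use_fdr,
            case_label=config.case_label,
            test=config.test,
        )
        diff.to_csv(out / "differential.tsv", sep="\t", index=False)
        diff_skipped.to_csv(out / "differential_skipped.tsv", sep="\t", index=False)
        sig = diff[diff["significant"]] if len(diff) else diff

        stage = "pca"
        pca_summary = None
        if len(sig) >= 2:
            site_idx = retained.site_index()
            sig_indices = [
                site_idx[(r.chrom, r.pos, r.strand)] for r in sig.itertuples()
            ]
            pca = pca_editing(retained, sig_indices)
            pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample")
            pca_summary = {
                "pct_pc1": float(pca.pct_variance[0]),
                "pct_pc2": float(pca.pct_variance[1]) if len(pca.pct_variance) > 1 else 0.0,
                "n_sites_used": pca.n_sites_used,
            }

        stage = "cis-regulation"
        lengths = effective_gene_lengths(annotation)
        expression = tpm(gene_counts, lengths)
        expression.round(4).to_csv(out / "tpm.tsv", sep="\t", index_label="gene_id")
        if config.cis_scope == "significant":
            cis_sites = [EditingSite(r.chrom, r.pos, r.strand) for r in sig.itertuples()]
        else:
            cis_sites = list(retained.sites)
        cis, cis_skipped = cis_scan(
            cis_sites, retained, expression, gene_map, p_cutoff=config.p_cutoff
        )
        cis.to_csv(out / "cis.tsv", sep="\t", index=False)
        cis_skipped.to_csv(out / "cis_skipped.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    edited_genes = sorted({g for g in gene_map.values() if g is not None})
    report = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_input_sites": int(len(counts.sites) + len(rejected)),
        "n_rejected_variants": int(len(rejected)),
        "n_retained_sites": int(len(retained.sites)),
        "n_edited_genes": len(edited_genes),
        "category_counts": {k: int(v) for k, v in categories.items()},
        "accounting": {
            "per_group_sites": accounting["per_group_sites"],
            "per_group_genes": accounting["per_group_genes"],
            "venn": accounting["venn"],
            "per_sample_sites": accounting["per_sample_sites"],
            "per_sample_genes": accounting["per_sample_genes"],
        },
        "context": _context_summary(enrichment, ctx),
        "differential": {
            "n_tested": int(len(diff)),
            "n_skipped": int(len(diff_skipped)),
            "n_significant": int(len(sig)),
            "n_up_in_case": int((sig["direction"] == "up_in_case").sum()) if len(sig) else 0,
            "n_down_in_case": int((sig["direction"] == "down_in_case").sum()) if len(sig) else 0,
            "n_genes_significant": len(
                {
                    gene_map.get((r.chrom, r.pos, r.strand))
                    for r in sig.itertuples()
                    if gene_map.get((r.chrom, r.pos, r.strand)) is not None
                }
            )
            if len(sig)
            else 0,
        },
        "pca": pca_summary,
        "cis": {
            "n_tested": int(len(cis)),
            "n_skipped": int(len(cis_skipped)),
            "n_significant": int(cis["significant"].sum()) if len(cis) else 0,
            "n_positive": int(((cis["significant"]) & (cis["direction"] == "positive")).sum())
            if len(cis)
            else 0,
            "n_negative": int(((cis["significant"]) & (cis["direction"] == "negative")).sum())
            if len(cis)
            else 0,
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %d retained sites", report["n_retained_sites"])
    return report


def _context_summary(enrichment: pd.DataFrame, ctx) -> dict:
    summary = {"n_sites_used": int(ctx.n_sites), "n_dropped": len(ctx.dropped)}
    if len(enrichment):
        for pos_label, pos in (("minus1_G", -1), ("plus1_G", 1)):
            row = enrichment[(enrichment["position"] == pos) & (enrichment["base"] == "G")]
            if len(row):
                r = row.iloc[0]
                summary[pos_label] = {
                    "odds_ratio": None if np.isnan(r["odds_ratio"]) else float(r["odds_ratio"]),
                    "p": float(r["p"]),
                    "q": float(r["q"]),
                    "direction": str(r["direction"]),
                }
    return summary
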