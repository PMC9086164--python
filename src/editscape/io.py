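"""Readers and writers for the pipeline's file dialects.

Formats: FASTA (pyfaidx), GTF subset (gffutils), per-sample site-count TSV,
minimal multi-sample VCF 4.2 with an AD FORMAT field (pysam for reading),
known-site TSV, gene-count TSV, sample-metadata TSV. All coordinates
1-based closed; all tables tab-separated with a header row.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam

from .core import EditingSite, GenomeAnnotation, SiteCountMatrix, TranscriptModel

COUNT_COLUMNS = ["chrom", "pos", "strand", "ref_base", "alt_base", "ref_count", "alt_count"]
KNOWN_COLUMNS = ["chrom", "pos", "ref", "ed", "strand"]


class FormatError(ValueError):
    """Malformed record in an input file."""


# ---------------------------------------------------------------------------
# site-count tables


def write_counts_tsv(counts: SiteCountMatrix, out_dir: str | Path) -> list[Path]:
    """One TSV per sample; ref/alt are plus-strand genomic bases."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, sample in enumerate(counts.samples):
        path = out_dir / f"{sample}.counts.tsv"
        with open(path, "w") as fh:
            fh.write("\t".join(COUNT_COLUMNS) + "\n")
            for i, site in enumerate(counts.sites):
                fh.write(
                    f"{site.chrom}\t{site.pos}\t{site.strand}\t"
                    f"{site.genomic_ref}\t{site.genomic_alt}\t"
                    f"{counts.ref_counts[i, j]}\t{counts.ed_counts[i, j]}\n"
                )
        paths.append(path)
    return paths


def _records_to_matrix(
    records: list[tuple[str, int, str, str, str, dict[str, tuple[int, int]]]],
    samples: list[str],
) -> tuple[SiteCountMatrix, pd.DataFrame]:
    """Canonicalize raw SNV records and assemble the count matrix.

    Each record is (chrom, pos, ref, alt, strand_hint, {sample: (ref_n, alt_n)}).
    Non A-to-G records are rejected with a reason, not fatal.
    """
    from .detection import canonicalize_variant

    per_site: dict[tuple[str, int, str], dict[str, tuple[int, int]]] = {}
    rejected = []
    for chrom, pos, ref, alt, hint, by_sample in records:
        result = canonicalize_variant(chrom, pos, ref, alt, strand_hint=hint)
        if isinstance(result, EditingSite):
            cell = per_site.setdefault(result.key, {})
            for sample, (rn, an) in by_sample.items():
                prev = cell.get(sample, (0, 0))
                cell[sample] = (prev[0] + rn, prev[1] + an)
        else:
            rejected.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "reason": result.reason}
            )
    keys = sorted(per_site)
    sites = [EditingSite(c, p, s) for c, p, s in keys]
    ref_counts = np.zeros((len(sites), len(samples)), dtype=np.int64)
    ed_counts = np.zeros_like(ref_counts)
    sample_idx = {s: j for j, s in enumerate(samples)}
    for i, key in enumerate(keys):
        for sample, (rn, an) in per_site[key].items():
            j = sample_idx[sample]
            ref_counts[i, j] = rn
            ed_counts[i, j] = an
    matrix = SiteCountMatrix(sites, list(samples), ref_counts, ed_counts)
    rej = pd.DataFrame(rejected, columns=["chrom", "pos", "ref", "alt", "reason"])
    return matrix, rej


def read_counts_tsv(
    paths: dict[str, str | Path],
) -> tuple[SiteCountMatrix, pd.DataFrame]:
    """Read per-sample count TSVs; returns (matrix, rejected-record log)."""
    records: dict[tuple[str, int, str, str, str], dict[str, tuple[int, int]]] = {}
    for sample, path in paths.items():
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != COUNT_COLUMNS:
                raise FormatError(f"{path}: unexpected header {header}")
            for lineno, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 7:
                    raise FormatError(f"{path}:{lineno}: expected 7 fields")
                chrom, pos_s, strand, ref, alt, rn_s, an_s = fields
                try:
                    pos, rn, an = int(pos_s), int(rn_s), int(an_s)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
                if pos < 1:
                    raise FormatError(f"{path}:{lineno}: coordinates are 1-based (pos={pos})")
                if rn < 0 or an < 0:
                    raise FormatError(f"{path}:{lineno}: negative counts")
                key = (chrom, pos, ref.upper(), alt.upper(), strand)
                records.setdefault(key, {})[sample] = (rn, an)
    samples = list(paths)
    rec_list = [
        (chrom, pos, ref, alt, hint, by_sample)
        for (chrom, pos, ref, alt, hint), by_sample in sorted(records.items())
    ]
    return _records_to_matrix(rec_list, samples)


def write_counts_vcf(
    counts: SiteCountMatrix, contig_lengths: dict[str, int], path: str | Path
) -> None:
    """Minimal VCF 4.2: one line per site, AD=ref,alt per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=STRAND,Number=1,Type=String,Description="Editing strand">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(counts.samples)
            + "\n"
        )
        order = sorted(range(len(counts.sites)), key=lambda i: counts.sites[i].key)
        for i in order:
            site = counts.sites[i]
            cells = "\t".join(
                f"{counts.ref_counts[i, j]},{counts.ed_counts[i, j]}"
                for j in range(len(counts.samples))
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.genomic_ref}\t{site.genomic_alt}\t"
                f".\tPASS\tSTRAND={site.strand}\tAD\t{cells}\n"
            )


def read_counts_vcf(path: str | Path) -> tuple[SiteCountMatrix, pd.DataFrame]:
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    records = []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        hint = rec.info.get("STRAND", None)
        by_sample = {}
        for sample in samples:
            ad = rec.samples[sample].get("AD")
            if ad is None or ad[0] is None:
                continue
            by_sample[sample] = (int(ad[0]), int(ad[1]))
        records.append((rec.chrom, rec.pos, rec.ref.upper(), rec.alts[0].upper(), hint, by_sample))
    vcf.close()
    return _records_to_matrix(records, samples)


def read_counts(path: str | Path, fmt: str | None = None):
    """Dispatch on format: a directory of per-sample TSVs, or one VCF."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.is_dir() else "vcf"
    if fmt == "tsv":
        paths = {p.name.replace(".counts.tsv", ""): p for p in sorted(path.glob("*.counts.tsv"))}
        if not paths:
            raise FileNotFoundError(f"no *.counts.tsv files under {path}")
        return read_counts_tsv(paths)
    if fmt == "vcf":
        return read_counts_vcf(path)
    raise ValueError(f"unknown counts format {fmt!r}")


# ---------------------------------------------------------------------------
# editing-level matrix


def write_levels(levels, path: str | Path) -> None:
    from .core import EditingLevelMatrix  # noqa: F401  (type only)

    with open(path, "w") as fh:
        fh.write(f"# min_coverage={levels.min_coverage}\n")
        levels.to_frame().to_csv(fh, sep="\t", index_label="site_id", na_rep="NA")


def read_levels(path: str | Path):
    from .core import EditingLevelMatrix, EditingSite

    min_coverage = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# min_coverage="):
            min_coverage = int(first.strip().split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t", index_col="site_id", na_values=["NA"])
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="site_id", na_values=["NA"])
    sites = []
    for label in df.index:
        chrom, pos, strand = str(label).rsplit(":", 2)
        sites.append(EditingSite(chrom, int(pos), strand))
    return EditingLevelMatrix(
        sites=sites,
        samples=[str(c) for c in df.columns],
        levels=df.to_numpy(dtype=float),
        min_coverage=min_coverage,
    )


# ---------------------------------------------------------------------------
# known-site table


def write_known_sites(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, KNOWN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_known_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(KNOWN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: known-site table lacks columns {sorted(missing)}")
    return df


def known_site_keys(table: pd.DataFrame, match_strand: bool = True) -> set:
    if match_strand:
        return set(zip(table["chrom"], table["pos"], table["strand"]))
    return set(zip(table["chrom"], table["pos"]))


# ---------------------------------------------------------------------------
# expression and metadata


def write_gene_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.loc[:, ["sample", "group"]].to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise FormatError(f"{path}: metadata needs 'sample' and 'group' columns")
    return df


# ---------------------------------------------------------------------------
# GTF subset


def _cds_frames(cds: list[tuple[int, int]], strand: str) -> list[int]:
    intervals = cds if strand == "+" else cds[::-1]
    frames, consumed = [], 0
    for s, e in intervals:
        frames.append((3 - consumed % 3) % 3)
        consumed += e - s + 1
    return frames if strand == "+" else frames[::-1]


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in annotation.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##format: gtf-subset\n")
        for gene_id in sorted(by_gene):
            transcripts = by_gene[gene_id]
            chrom = transcripts[0].chrom
            strand = transcripts[0].strand
            biotype = transcripts[0].gene_biotype
            gstart = min(t.start for t in transcripts)
            gend = max(t.end for t in transcripts)
            attrs = f'gene_id "{gene_id}"; gene_biotype "{biotype}";'
            fh.write(f"{chrom}\teditscape\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t{attrs}\n")
            for t in sorted(transcripts, key=lambda t: t.transcript_id):
                tattrs = (
                    f'gene_id "{gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "{biotype}";'
                )
                fh.write(
                    f"{chrom}\teditscape\ttranscript\t{t.start}\t{t.end}\t.\t{strand}\t.\t{tattrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{chrom}\teditscape\texon\t{s}\t{e}\t.\t{strand}\t.\t{tattrs}\n"
                    )
                for (s, e), frame in zip(t.cds, _cds_frames(t.cds, strand)):
                    fh.write(
                        f"{chrom}\teditscape\tCDS\t{s}\t{e}\t.\t{strand}\t{frame}\t{tattrs}\n"
                    )


def read_gtf(path: str | Path) -> GenomeAnnotation:
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except gffutils.exceptions.EmptyInputError:  # valid, empty annotation
        return GenomeAnnotation([])
    transcripts = []
    for t in db.features_of_type("transcript"):
        exons = [(f.start, f.end) for f in db.children(t, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(t, featuretype="CDS")]
        transcripts.append(
            TranscriptModel(
                gene_id=t.attributes["gene_id"][0],
                transcript_id=t.attributes["transcript_id"][0],
                chrom=t.seqid,
                strand=t.strand,
                exons=exons,
                cds=cds,
                gene_biotype=t.attributes.get("gene_biotype", ["protein_coding"])[0],
            )
        )
    return GenomeAnnotation(transcripts)
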