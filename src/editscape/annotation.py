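"""Functional-consequence annotation of editing sites against a transcript model.

Each retained site receives exactly one category. Within a coding
transcript the edited adenosine is classified by containment (UTR / CDS /
intron); in the CDS, the codon is rebuilt with G substituted for the
edited A and translated with the standard genetic code to distinguish
synonymous, missense and stop-lost changes. Across overlapping
transcripts the most severe call wins, under the fixed order

    stop_lost > missense > synonymous > 5'UTR > 3'UTR
    > non-coding exon > intron > non-coding intron > intergenic

Only transcripts on the site's own strand are considered: an A-to-G
editing site is by construction on the transcribed strand of its host
gene, and a site lying solely inside antisense annotation is reported as
intergenic for its own strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .core import CATEGORIES, SEVERITY, EditingSite, GenomeAnnotation, TranscriptModel
from .genome import Genome


@dataclass(frozen=True)
class ConsequenceCall:
    site: EditingSite
    category: str
    gene_id: str | None = None
    transcript_id: str | None = None
    codon_change: str | None = None  # e.g. "AAA>AGA" (sense strand)
    aa_change: str | None = None  # e.g. "K>R"
    ref_mismatch: bool = False  # reference base at site was not A (stranded)


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _classify_in_transcript(
    site: EditingSite, t: TranscriptModel, genome: Genome
) -> tuple[str, str | None, str | None]:
    """(category, codon_change, aa_change) for one containing transcript."""
    pos = site.pos
    if not t.in_exon(pos):
        return (
            "intron_variant" if t.coding else "non_coding_transcript_intron_variant",
            None,
            None,
        )
    if not t.coding:
        return "non_coding_transcript_exon_variant", None, None
    if not t.in_cds(pos):
        # exonic but outside the CDS: which UTR depends on transcript orientation
        cds_start, cds_end = t.cds[0][0], t.cds[-1][1]
        if t.strand == "+":
            return ("5_prime_UTR_variant" if pos < cds_start else "3_prime_UTR_variant"), None, None
        return ("5_prime_UTR_variant" if pos > cds_end else "3_prime_UTR_variant"), None, None

    cds_pos = t.cds_positions()
    idx = cds_pos.index(pos)
    codon_i = idx // 3
    codon_genomic = cds_pos[codon_i * 3 : codon_i * 3 + 3]
    if len(codon_genomic) < 3:  # truncated terminal codon; treat as coding, no call
        return "synonymous_variant", None, None
    ref_codon = "".join(genome.stranded_base(t.chrom, p, t.strand) for p in codon_genomic)
    offset = idx % 3
    alt_codon = ref_codon[:offset] + "G" + ref_codon[offset + 1 :]
    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    if ref_aa == "*" and alt_aa != "*":
        cat = "stop_lost"
    elif ref_aa == alt_aa:
        cat = "synonymous_variant"
    else:
        cat = "missense_variant"
    return cat, f"{ref_codon}>{alt_codon}", f"{ref_aa}>{alt_aa}"


def annotate_site(
    site: EditingSite, annotation: GenomeAnnotation, genome: Genome
) -> ConsequenceCall:
    """Assign the single most severe consequence for a site."""
    if site.chrom not in genome:
        raise ValueError(f"site chromosome {site.chrom!r} absent from the reference")
    ref_mismatch = genome.stranded_base(site.chrom, site.pos, site.strand) != "A"

    candidates = []
    for t in annotation.overlapping(site.chrom, site.pos):
        if t.strand != site.strand:
            continue
        cat, codon_change, aa_change = _classify_in_transcript(site, t, genome)
        candidates.append((SEVERITY[cat], t.gene_id, t.transcript_id, cat, codon_change, aa_change))
    if not candidates:
        return ConsequenceCall(site, "intergenic_variant", ref_mismatch=ref_mismatch)
    candidates.sort()
    _, gene_id, transcript_id, cat, codon_change, aa_change = candidates[0]
    return ConsequenceCall(
        site,
        cat,
        gene_id=gene_id,
        transcript_id=transcript_id,
        codon_change=codon_change,
        aa_change=aa_change,
        ref_mismatch=ref_mismatch,
    )


def annotate_sites(
    sites, annotation: GenomeAnnotation, genome: Genome
) -> list[ConsequenceCall]:
    return [annotate_site(s, annotation, genome) for s in sites]


def tabulate_categories(calls) -> pd.Series:
    """Counts over the nine categories; always sums to len(calls)."""
    counts = pd.Series(0, index=list(CATEGORIES), dtype=int)
    for call in calls:
        counts[call.category] += 1
    return counts


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.site.chrom for c in calls],
            "pos": [c.site.pos for c in calls],
            "strand": [c.site.strand for c in calls],
            "category": [c.category for c in calls],
            "gene_id": [c.gene_id for c in calls],
            "transcript_id": [c.transcript_id for c in calls],
            "codon_change": [c.codon_change for c in calls],
            "aa_change": [c.aa_change for c in calls],
            "ref_mismatch": [c.ref_mismatch for c in calls],
        }
    )


def gene_map_from_calls(calls) -> dict:
    """site key -> host gene_id (None for intergenic sites)."""
    return {c.site.key: c.gene_id for c in calls}
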