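"""Editing-level quantification and the high-confidence site filter.

The editing level at a site in a sample is the fraction of reads
supporting the edited base, G/(A+G) after strand adjustment. A candidate
site is retained as high-confidence when its level is at least
``min_level`` (default 1%) in at least ``min_samples`` samples (default
2), or when it is catalogued in a known-editing-site table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EditingLevelMatrix, EditingSite, GenomeAnnotation, SiteCountMatrix

NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class Rejection:
    """Why a candidate variant was not accepted as an editing site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    reason: str


def compute_editing_level(
    ref_count: int, ed_count: int, min_coverage: int = 10
) -> float:
    """Editing level ed/(ref+ed), or NaN below the coverage floor.

    A cell under ``min_coverage`` total A+G reads carries too little
    information to test the 1% threshold, so it is *missing* rather than
    zero.
    """
    if ref_count < 0 or ed_count < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_count + ed_count
    if total < min_coverage:
        return float("nan")
    return ed_count / total


def compute_levels(counts: SiteCountMatrix, min_coverage: int = 10) -> EditingLevelMatrix:
    """Vectorized editing levels for a whole count matrix."""
    total = counts.coverage.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(total > 0, counts.ed_counts / np.maximum(total, 1), 0.0)
    levels = np.where(total >= min_coverage, levels, np.nan)
    return EditingLevelMatrix(
        sites=list(counts.sites),
        samples=list(counts.samples),
        levels=levels,
        min_coverage=min_coverage,
    )


def canonicalize_variant(
    chrom: str,
    pos: int,
    ref_base: str,
    alt_base: str,
    strand_hint: str | None = None,
    annotation: GenomeAnnotation | None = None,
    allow_antisense: bool = False,
) -> EditingSite | Rejection:
    """Map an SNV to a canonical A-to-G editing site or reject it.

    A>G implies editing on '+'; T>C implies editing on '-'. The strand of
    an overlapping gene wins when an annotation is supplied; unannotated
    positions fall back to the substitution-implied strand (or the caller's
    hint when the substitution alone cannot decide, which never happens for
    SNVs). A-to-G antisense to the host gene is rejected by default: ADAR
    acts on transcribed (sense) adenosines.
    """
    ref_base = ref_base.upper()
    alt_base = alt_base.upper()
    if (
        len(ref_base) != 1
        or len(alt_base) != 1
        or ref_base not in NUCLEOTIDES
        or alt_base not in NUCLEOTIDES
    ):
        raise ValueError(f"not a single-nucleotide substitution: {ref_base}>{alt_base}")
    if ref_base == alt_base:
        raise ValueError(f"ref and alt are identical: {ref_base}")
    if pos < 1:
        raise ValueError(f"coordinates are 1-based; got pos={pos}")

    if (ref_base, alt_base) == ("A", "G"):
        implied = "+"
    elif (ref_base, alt_base) == ("T", "C"):
        implied = "-"
    else:
        return Rejection(chrom, pos, ref_base, alt_base, "not A-to-G under either strand")

    gene_strand = annotation.gene_strand(chrom, pos) if annotation is not None else None
    if gene_strand is None:
        strand = implied if strand_hint not in ("+", "-") else strand_hint
        if strand != implied:
            # hint says the transcript runs the other way: antisense A-to-G
            if not allow_antisense:
                return Rejection(
                    chrom, pos, ref_base, alt_base, "antisense A-to-G (strand hint)"
                )
            strand = implied
    elif gene_strand != implied:
        if not allow_antisense:
            return Rejection(
                chrom, pos, ref_base, alt_base, "antisense A-to-G within gene"
            )
        strand = implied
    else:
        strand = implied
    return EditingSite(chrom, pos, strand)


def filter_high_confidence(
    levels: EditingLevelMatrix,
    known_keys: set | None = None,
    min_level: float = 0.01,
    min_samples: int = 2,
    match_strand: bool = True,
) -> tuple[EditingLevelMatrix, pd.DataFrame]:
    """Apply the high-confidence filter; returns (retained, decision log).

    Retained iff (#samples with defined level >= min_level) >= min_samples,
    OR the site is in the known table. The log records which branch fired
    for every input site.
    """
    known_keys = known_keys or set()
    defined = levels.mask
    above = defined & (np.nan_to_num(levels.levels, nan=-1.0) >= min_level)
    n_above = above.sum(axis=1)

    rows = []
    keep = []
    for i, site in enumerate(levels.sites):
        key = site.key if match_strand else (site.chrom, site.pos)
        by_threshold = int(n_above[i]) >= min_samples
        by_known = key in known_keys
        retained = by_threshold or by_known
        if by_threshold and by_known:
            branch = "threshold+known"
        elif by_threshold:
            branch = "threshold"
        elif by_known:
            branch = "known"
        else:
            branch = "removed"
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "strand": site.strand,
                "n_samples_above": int(n_above[i]),
                "is_known": by_known,
                "retained": retained,
                "branch": branch,
            }
        )
        if retained:
            keep.append(i)
    retained_levels = levels.subset(keep)
    retained_levels.sites = [
        s.with_known((s.key if match_strand else (s.chrom, s.pos)) in known_keys)
        for s in retained_levels.sites
    ]
    return retained_levels, pd.DataFrame(rows)


def group_site_accounting(
    levels: EditingLevelMatrix,
    metadata: pd.DataFrame,
    gene_map: dict | None = None,
    min_level: float = 0.01,
    detect_min_samples: int = 1,
) -> dict:
    """Per-group detection counts and the exclusive/shared Venn partition.

    A site is "detected in group g" when at least ``detect_min_samples``
    samples of g have a defined level >= ``min_level``. Sites retained only
    through the known-site branch can be detected in neither group; they
    are reported under ``neither`` so the partition still sums to the
    retained total.
    """
    groups = list(dict.fromkeys(metadata["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    sample_to_group = dict(zip(metadata["sample"], metadata["group"]))
    for g in groups:
        if sum(1 for s in levels.samples if sample_to_group.get(s) == g) == 0:
            raise ValueError(f"group {g!r} has no samples in the level matrix")

    detected = np.zeros((len(levels.sites), 2), dtype=bool)
    per_sample_sites = {}
    above = levels.mask & (np.nan_to_num(levels.levels, nan=-1.0) >= min_level)
    for j, sample in enumerate(levels.samples):
        per_sample_sites[sample] = int(above[:, j].sum())
    for gi, g in enumerate(groups):
        cols = [j for j, s in enumerate(levels.samples) if sample_to_group.get(s) == g]
        detected[:, gi] = above[:, cols].sum(axis=1) >= detect_min_samples

    both = detected.all(axis=1)
    only_a = detected[:, 0] & ~detected[:, 1]
    only_b = detected[:, 1] & ~detected[:, 0]
    neither = ~detected.any(axis=1)

    def genes_of(mask: np.ndarray) -> int:
        if gene_map is None:
            return 0
        hit = {
            gene_map.get(levels.sites[i].key)
            for i in np.flatnonzero(mask)
            if gene_map.get(levels.sites[i].key) is not None
        }
        return len(hit)

    per_sample_genes = {}
    if gene_map is not None:
        for j, sample in enumerate(levels.samples):
            per_sample_genes[sample] = genes_of(above[:, j])

    return {
        "groups": groups,
        "total_sites": len(levels.sites),
        "per_group_sites": {g: int(detected[:, gi].sum()) for gi, g in enumerate(groups)},
        "per_group_genes": {
            groups[0]: genes_of(detected[:, 0]),
            groups[1]: genes_of(detected[:, 1]),
        },
        "venn": {
            f"{groups[0]}_exclusive": int(only_a.sum()),
            f"{groups[1]}_exclusive": int(only_b.sum()),
            "shared": int(both.sum()),
            "neither": int(neither.sum()),
        },
        "per_sample_sites": per_sample_sites,
        "per_sample_genes": per_sample_genes,
    }
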