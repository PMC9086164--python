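"""Core containers for A-to-I editing analysis.

Coordinates are 1-based and fully closed everywhere (GTF/VCF convention).
Sites are stored canonically on the edited strand: the reference base is
always A and the edited base always G; a site observed as T>C on the plus
strand of the genome is stored as (A, G) with strand '-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CATEGORIES = (
    "stop_lost",
    "missense_variant",
    "synonymous_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "non_coding_transcript_intron_variant",
    "intergenic_variant",
)
#: lower = more severe; used to pick one call per site across transcripts
SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True, order=True)
class EditingSite:
    """A canonical A-to-G editing site.

    ``strand`` is the strand on which the edited adenosine lies; ``ref_base``
    and ``ed_base`` are given on that strand and are (A, G) for every valid
    instance.
    """

    chrom: str
    pos: int  # 1-based
    strand: str  # '+' or '-'
    ref_base: str = "A"
    ed_base: str = "G"
    is_known: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got pos={self.pos}")
        if (self.ref_base, self.ed_base) != ("A", "G"):
            raise ValueError(
                "EditingSite stores canonical A-to-G only; "
                f"got {self.ref_base}>{self.ed_base}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)

    @property
    def genomic_ref(self) -> str:
        """Reference base as it appears on the plus strand of the genome."""
        return "A" if self.strand == "+" else "T"

    @property
    def genomic_alt(self) -> str:
        return "G" if self.strand == "+" else "C"

    def with_known(self, flag: bool) -> "EditingSite":
        return replace(self, is_known=flag)

    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


@dataclass
class SiteCountMatrix:
    """Per-sample A-supporting and G-supporting read counts at each site."""

    sites: list[EditingSite]
    samples: list[str]
    ref_counts: np.ndarray  # (n_sites, n_samples) int
    ed_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.ed_counts = np.asarray(self.ed_counts, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        if self.ref_counts.shape != shape or self.ed_counts.shape != shape:
            raise ValueError(
                f"count matrices must have shape {shape}; got "
                f"{self.ref_counts.shape} and {self.ed_counts.shape}"
            )
        if (self.ref_counts < 0).any() or (self.ed_counts < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def coverage(self) -> np.ndarray:
        return self.ref_counts + self.ed_counts

    def site_index(self) -> dict[tuple[str, int, str], int]:
        return {s.key: i for i, s in enumerate(self.sites)}

    def subset(self, indices: Sequence[int]) -> "SiteCountMatrix":
        idx = list(indices)
        return SiteCountMatrix(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            ref_counts=self.ref_counts[idx],
            ed_counts=self.ed_counts[idx],
        )


@dataclass
class EditingLevelMatrix:
    """Editing levels G/(A+G) with missingness below a coverage floor.

    ``levels[i, j]`` is NaN when sample j has fewer than ``min_coverage``
    A+G reads at site i — the level is then *unknown*, not zero, and takes
    no part in threshold tests.
    """

    sites: list[EditingSite]
    samples: list[str]
    levels: np.ndarray  # (n_sites, n_samples) float, NaN = missing
    min_coverage: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        shape = (len(self.sites), len(self.samples))
        if self.levels.shape != shape:
            raise ValueError(f"levels must have shape {shape}")
        defined = self.levels[~np.isnan(self.levels)]
        if defined.size and ((defined < 0) | (defined > 1)).any():
            raise ValueError("defined editing levels must lie in [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, True where the level is defined."""
        return ~np.isnan(self.levels)

    def site_index(self) -> dict[tuple[str, int, str], int]:
        return {s.key: i for i, s in enumerate(self.sites)}

    def subset(self, indices: Sequence[int]) -> "EditingLevelMatrix":
        idx = list(indices)
        return EditingLevelMatrix(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            levels=self.levels[idx],
            min_coverage=self.min_coverage,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.levels,
            index=[s.label() for s in self.sites],
            columns=self.samples,
        )


@dataclass
class TranscriptModel:
    """One transcript: sorted 1-based closed exon intervals, optional CDS."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    gene_biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS not contained in exons")

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def cds_positions(self) -> list[int]:
        """Genomic positions of the CDS in translation (5'→3') order."""
        pos = [p for s, e in self.cds for p in range(s, e + 1)]
        return pos if self.strand == "+" else pos[::-1]

    def exon_positions(self) -> list[int]:
        pos = [p for s, e in self.exons for p in range(s, e + 1)]
        return pos if self.strand == "+" else pos[::-1]


class GenomeAnnotation:
    """A set of transcript models with per-chromosome interval lookup."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts = sorted(
            transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)
        )
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.transcripts:
            seen.setdefault(t.gene_id, None)
        return list(seen)

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        # linear scan within chromosome; fine at the gene counts this
        # package targets (hundreds per contig)
        return [t for t in self._by_chrom.get(chrom, []) if t.contains(pos)]

    def gene_strand(self, chrom: str, pos: int) -> str | None:
        """Strand of the gene(s) overlapping pos; None if absent/ambiguous."""
        strands = {t.strand for t in self.overlapping(chrom, pos)}
        if len(strands) == 1:
            return strands.pop()
        return None
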