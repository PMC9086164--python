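"""In-memory genome with 1-based closed-interval access.

The genomes this package works with (reference subsets, simulated contigs)
are small enough to hold in memory as numpy character arrays, which also
lets the simulator rewrite single bases when planting editing sites.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from pyfaidx import Fasta

from .core import COMPLEMENT, revcomp


class Genome:
    def __init__(self, seqs: dict[str, str]):
        self._arrays: dict[str, np.ndarray] = {
            chrom: np.array(list(seq.upper()), dtype="<U1")
            for chrom, seq in seqs.items()
        }

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        genome = cls({name: str(fa[name][:]) for name in fa.keys()})
        fa.close()
        return genome

    @property
    def chroms(self) -> list[str]:
        return list(self._arrays)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._arrays

    def __iter__(self) -> Iterator[str]:
        return iter(self._arrays)

    def length(self, chrom: str) -> int:
        return len(self._arrays[chrom])

    def sequence(self, chrom: str) -> str:
        return "".join(self._arrays[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position, plus strand."""
        return str(self._arrays[chrom][pos - 1])

    def set_base(self, chrom: str, pos: int, base: str) -> None:
        self._arrays[chrom][pos - 1] = base.upper()

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence for the 1-based closed interval [start, end]."""
        if start < 1 or end > self.length(chrom):
            raise IndexError(
                f"{chrom}:{start}-{end} outside contig of length {self.length(chrom)}"
            )
        return "".join(self._arrays[chrom][start - 1 : end])

    def stranded_base(self, chrom: str, pos: int, strand: str) -> str:
        b = self.base(chrom, pos)
        return b if strand == "+" else COMPLEMENT[b]

    def set_stranded_base(self, chrom: str, pos: int, strand: str, base: str) -> None:
        self.set_base(chrom, pos, base if strand == "+" else COMPLEMENT[base])

    def composition(self) -> dict[str, float]:
        """Genome-wide base frequencies over A, C, G, T."""
        counts = {b: 0 for b in "ACGT"}
        for arr in self._arrays.values():
            vals, n = np.unique(arr, return_counts=True)
            for v, c in zip(vals, n):
                if v in counts:
                    counts[v] += int(c)
        total = sum(counts.values())
        return {b: c / total for b, c in counts.items()}

    def reverse_complement(self) -> "Genome":
        return Genome({c: revcomp(self.sequence(c)) for c in self.chroms})

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                fh.write(f">{chrom}\n")
                seq = self.sequence(chrom)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
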