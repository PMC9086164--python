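"""Nucleotide preference around editing sites.

ADAR shows a nearest-neighbour preference: G is depleted immediately 5'
of the edited adenosine and enriched immediately 3' of it. This module
extracts strand-adjusted windows (default +/-6 bp, 13-mers) around sites,
builds a position frequency matrix, and tests each (position, base) cell
for enrichment or depletion against a background composition with a
two-sided Fisher exact test, BH-adjusted across all cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import EditingSite, revcomp
from .genome import Genome

BASES = "ACGT"


@dataclass
class ContextMatrix:
    """Per-position nucleotide counts over aligned, strand-adjusted windows."""

    flank: int
    counts: pd.DataFrame  # index: BASES, columns: -flank..+flank
    n_sites: int
    dropped: list[EditingSite] = field(default_factory=list)

    @property
    def positions(self) -> list[int]:
        return list(self.counts.columns)

    def frequencies(self) -> pd.DataFrame:
        if self.n_sites == 0:
            return self.counts.astype(float)
        return self.counts / self.n_sites


def extract_contexts(
    sites, genome: Genome, flank: int = 6
) -> ContextMatrix:
    """Strand-adjusted windows around sites; minus-strand windows are
    reverse-complemented so upstream (negative positions) is always 5' of
    the edited A. Sites too close to a contig end are dropped and logged."""
    positions = list(range(-flank, flank + 1))
    base_row = {b: i for i, b in enumerate(BASES)}
    counts = np.zeros((4, len(positions)), dtype=int)
    dropped: list[EditingSite] = []
    n = 0
    for site in sites:
        start, end = site.pos - flank, site.pos + flank
        if start < 1 or end > genome.length(site.chrom):
            dropped.append(site)
            continue
        window = genome.fetch(site.chrom, start, end)
        if site.strand == "-":
            window = revcomp(window)
        for col, b in enumerate(window):
            row = base_row.get(b)
            if row is not None:
                counts[row, col] += 1
        n += 1
    frame = pd.DataFrame(counts, index=list(BASES), columns=positions)
    return ContextMatrix(flank=flank, counts=frame, n_sites=n, dropped=dropped)


def genome_background(genome: Genome) -> dict[str, float]:
    return genome.composition()


UNIFORM_BACKGROUND = {b: 0.25 for b in BASES}


def position_enrichment(
    observed: ContextMatrix,
    background: dict[str, float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (position, base) Fisher exact test against background.

    The 2x2 table contrasts the observed count of base b at position p
    (vs other bases) with the expected split under the background
    frequencies, rounded to counts on the same n. Position 0 is the edited
    A itself and is excluded. Returns one row per cell with odds ratio,
    two-sided p, BH-adjusted q and a direction flag.
    """
    total_bg = sum(background.get(b, 0.0) for b in BASES)
    if not np.isclose(total_bg, 1.0, atol=1e-6):
        raise ValueError(f"background frequencies must sum to 1, got {total_bg}")
    n = observed.n_sites
    if n < 1:
        raise ValueError("need at least one site with a full window")
    rows = []
    for p in observed.positions:
        if p == 0:
            continue
        for b in BASES:
            obs = int(observed.counts.loc[b, p])
            exp = int(round(background[b] * n))
            table = np.array([[obs, n - obs], [exp, n - exp]])
            if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
                odds, pval, flagged = np.nan, 1.0, True
            else:
                odds, pval = stats.fisher_exact(table, alternative="two-sided")
                flagged = False
            if np.isnan(odds) or flagged:
                direction = "undefined"
            elif odds > 1:
                direction = "enriched"
            elif odds < 1:
                direction = "depleted"
            else:
                direction = "none"
            rows.append(
                {
                    "position": p,
                    "base": b,
                    "observed": obs,
                    "expected": background[b] * n,
                    "odds_ratio": odds,
                    "p": pval,
                    "direction": direction,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["q"] < alpha
    return df
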