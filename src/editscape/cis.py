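"""Editing-expression cis correlation and TPM normalisation.

A site exerts a cis-regulatory effect when its editing level covaries
with the expression of its host gene across samples. Expression is
length- and depth-normalised to TPM (transcripts per million); the
association is the Spearman rank correlation with a two-sided t
approximation for the p-value, computed over samples where both the
level and the expression are defined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import EditingLevelMatrix, GenomeAnnotation
from .differential import benjamini_hochberg


def effective_gene_lengths(annotation: GenomeAnnotation) -> pd.Series:
    """Per gene: summed exon length of its longest (most exonic bp) transcript."""
    best: dict[str, int] = {}
    for t in annotation.transcripts:
        length = t.exonic_length
        if length > best.get(t.gene_id, 0):
            best[t.gene_id] = length
    return pd.Series(best, name="effective_length").sort_index()


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM per sample: (count/length) scaled to sum to 1e6.

    Samples with zero total counts get all-NaN columns (undefined, flagged
    by the caller via ``isna``).
    """
    missing = set(counts.index) - set(lengths.index)
    if missing:
        raise ValueError(f"no effective length for genes: {sorted(missing)[:5]} ...")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lens = lengths.loc[counts.index].astype(float)
    if (lens <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.div(lens, axis=0)
    totals = rate.sum(axis=0)
    out = rate.div(totals.where(totals > 0), axis=1) * 1e6
    return out


def spearman(x, y, min_n: int = 4) -> tuple[float, float, int]:
    """Spearman rho and two-sided p over complete pairs; (rho, p, n).

    Pairs with a missing member are dropped; rho is NaN (flagged) when
    fewer than ``min_n`` pairs remain or either variable has zero rank
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < min_n:
        return float("nan"), float("nan"), n
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n


def cis_scan(
    sites,
    levels: EditingLevelMatrix,
    expression: pd.DataFrame,
    gene_map: dict,
    p_cutoff: float = 0.05,
    min_n: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman(level, host-gene TPM) per site; returns (results, skipped).

    ``sites`` is an iterable of EditingSite restricted upstream (the study
    scans its differentially edited sites); ``gene_map`` maps site keys to
    host gene ids from the consequence annotation.
    """
    site_idx = levels.site_index()
    common_samples = [s for s in levels.samples if s in expression.columns]
    expr = expression.loc[:, common_samples]
    cols = [levels.samples.index(s) for s in common_samples]

    rows, skipped = [], []
    for site in sites:
        key = site.key
        gene = gene_map.get(key)
        if gene is None:
            skipped.append({"site": site.label(), "reason": "no host gene"})
            continue
        if key not in site_idx:
            skipped.append({"site": site.label(), "reason": "site absent from level matrix"})
            continue
        if gene not in expr.index:
            skipped.append({"site": site.label(), "reason": f"gene {gene} not in expression"})
            continue
        x = levels.levels[site_idx[key], cols]
        y = expr.loc[gene].to_numpy(dtype=float)
        rho, p, n = spearman(x, y, min_n=min_n)
        if np.isnan(rho):
            reason = (
                "zero variance in level or expression" if n >= min_n else f"fewer than {min_n} pairs"
            )
            skipped.append({"site": site.label(), "reason": reason})
            continue
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "strand": site.strand,
                "gene": gene,
                "n": n,
                "rho": rho,
                "p": p,
            }
        )
    results = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "gene", "n", "rho", "p"]
    )
    if len(results):
        results["q"] = benjamini_hochberg(results["p"])
        results["significant"] = results["p"] < p_cutoff
        results["direction"] = np.where(results["rho"] > 0, "positive", "negative")
    else:
        results["q"] = []
        results["significant"] = []
        results["direction"] = []
    return results, pd.DataFrame(skipped, columns=["site", "reason"])
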