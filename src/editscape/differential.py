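"""Group-wise differential editing: Kruskal-Wallis scan, BH adjustment, PCA.

Editing levels are bounded fractions with missing cells, so the group
comparison is the rank-based Kruskal-Wallis test (chi-square
approximation, tie-corrected), applied per site over the samples where
the level is defined. Direction of change is the sign of the case-minus-
control mean among significant sites. Sample structure is summarized by
PCA on the (imputed, centered) site-by-sample level matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import EditingLevelMatrix


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate input (all pooled values identical) is a defined no-signal
    outcome: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size == 0:
            raise ValueError("every group needs at least one defined value")
        if np.isnan(g).any():
            raise ValueError("missing values must be removed before testing")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def welch_t(a, b) -> tuple[float, float]:
    """Welch two-sample t-test; sensitivity analysis only."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)


def benjamini_hochberg(pvals) -> np.ndarray:
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def differential_scan(
    levels: EditingLevelMatrix,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    min_per_group: int = 3,
    use_fdr: bool = False,
    case_label: str | None = None,
    test: str = "kw",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site two-group test over defined levels.

    Sites with fewer than ``min_per_group`` defined values in either group
    are skipped (the chi-square approximation is unreliable at tiny n) and
    reported separately. Significance defaults to raw p < alpha; with
    ``use_fdr`` the BH-adjusted p is used instead.

    Returns (results, skipped).
    """
    groups = list(dict.fromkeys(metadata["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    if case_label is None:
        case_label = (
            "case" if "case" in groups else ("sepsis" if "sepsis" in groups else groups[0])
        )
    control_label = next(g for g in groups if g != case_label)
    sample_to_group = dict(zip(metadata["sample"], metadata["group"]))
    case_cols = [j for j, s in enumerate(levels.samples) if sample_to_group.get(s) == case_label]
    ctrl_cols = [
        j for j, s in enumerate(levels.samples) if sample_to_group.get(s) == control_label
    ]
    if not case_cols or not ctrl_cols:
        raise ValueError("both groups need at least one sample in the level matrix")

    rows, skipped = [], []
    for i, site in enumerate(levels.sites):
        row_levels = levels.levels[i]
        case_vals = row_levels[case_cols]
        ctrl_vals = row_levels[ctrl_cols]
        case_vals = case_vals[~np.isnan(case_vals)]
        ctrl_vals = ctrl_vals[~np.isnan(ctrl_vals)]
        if len(case_vals) < min_per_group or len(ctrl_vals) < min_per_group:
            skipped.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "strand": site.strand,
                    "reason": f"fewer than {min_per_group} defined values in a group",
                }
            )
            continue
        if test == "kw":
            stat, p = kruskal_wallis(case_vals, ctrl_vals)
        elif test == "t":
            stat, p = welch_t(case_vals, ctrl_vals)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "strand": site.strand,
                "n_case": len(case_vals),
                "n_control": len(ctrl_vals),
                "mean_case": float(np.mean(case_vals)),
                "mean_control": float(np.mean(ctrl_vals)),
                "median_case": float(np.median(case_vals)),
                "median_control": float(np.median(ctrl_vals)),
                "H": stat,
                "p": p,
            }
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "n_case", "n_control",
            "mean_case", "mean_control", "median_case", "median_control", "H", "p",
        ],
    )
    if len(results):
        results["q"] = benjamini_hochberg(results["p"])
        results["significant"] = (
            results["q"] < alpha if use_fdr else results["p"] < alpha
        )
        delta = results["mean_case"] - results["mean_control"]
        results["direction"] = np.where(
            ~results["significant"], "none", np.where(delta > 0, "up_in_case", "down_in_case")
        )
    else:
        results["q"] = []
        results["significant"] = []
        results["direction"] = []
    return results, pd.DataFrame(skipped, columns=["chrom", "pos", "strand", "reason"])


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x PCs
    pct_variance: np.ndarray  # per PC, sums to 100 over all PCs
    n_sites_used: int


def pca_editing(
    levels: EditingLevelMatrix,
    site_indices=None,
    max_missing_fraction: float = 0.5,
    scale: bool = False,
) -> PcaResult:
    """PCA of samples over (a subset of) sites.

    Sites missing in more than ``max_missing_fraction`` of samples are
    dropped; remaining missing cells take the site mean (which then
    contributes nothing after centering). Deterministic sign convention:
    within each PC the loading of largest magnitude is made positive.
    """
    sub = levels if site_indices is None else levels.subset(site_indices)
    if len(sub.sites) < 2 or len(sub.samples) < 2:
        raise ValueError("PCA needs at least two sites and two samples")
    x = sub.levels.T.copy()  # samples x sites
    miss_frac = np.isnan(x).mean(axis=0)
    x = x[:, miss_frac <= max_missing_fraction]
    if x.shape[1] < 2:
        raise ValueError("fewer than two sites pass the missingness threshold")
    col_mean = np.nanmean(x, axis=0)
    nan_idx = np.where(np.isnan(x))
    x[nan_idx] = np.take(col_mean, nan_idx[1])
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        x = x[:, keep] / sd[keep]
    if not np.any(x != 0):
        raise ValueError("level matrix has zero variance; PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # fix signs: largest-|loading| element of each PC positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    var = s**2
    pct = 100 * var / var.sum()
    n_pcs = scores.shape[1]
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=sub.samples, columns=[f"PC{k+1}" for k in range(n_pcs)]
        ),
        pct_variance=pct,
        n_sites_used=x.shape[1],
    )
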