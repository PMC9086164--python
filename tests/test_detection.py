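"""Editing-level computation, canonicalization policy, high-confidence filter."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import filter_decisions_bruteforce

from editscape.core import EditingLevelMatrix, EditingSite, GenomeAnnotation, TranscriptModel
from editscape.detection import (
    Rejection,
    canonicalize_variant,
    compute_editing_level,
    compute_levels,
    filter_high_confidence,
    group_site_accounting,
)


def _level_matrix(levels, min_coverage=10, samples=None):
    levels = np.asarray(levels, dtype=float)
    sites = [EditingSite("chr1", 10 * (i + 1), "+") for i in range(levels.shape[0])]
    samples = samples or [f"s{j}" for j in range(levels.shape[1])]
    return EditingLevelMatrix(sites, samples, levels, min_coverage)


@pytest.mark.parametrize(
    "ref,ed,min_cov,expected",
    [
        (90, 10, 10, 0.10),
        (99, 1, 10, 0.01),  # exactly at the 1% filter threshold
        (3, 1, 10, math.nan),  # below the coverage floor: missing, not zero
        (0, 10, 10, 1.0),
        (10, 0, 10, 0.0),
    ],
)
def test_compute_editing_level(ref, ed, min_cov, expected):
    got = compute_editing_level(ref, ed, min_cov)
    if math.isnan(expected):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(expected)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        compute_editing_level(-1, 5, 10)


def test_compute_levels_matches_scalar_rule(rng):
    ref = rng.integers(0, 30, size=(20, 6))
    ed = rng.integers(0, 30, size=(20, 6))
    from editscape.core import SiteCountMatrix

    counts = SiteCountMatrix(
        [EditingSite("chr1", i + 1, "+") for i in range(20)],
        [f"s{j}" for j in range(6)],
        ref,
        ed,
    )
    levels = compute_levels(counts, min_coverage=10)
    for i in range(20):
        for j in range(6):
            expected = compute_editing_level(int(ref[i, j]), int(ed[i, j]), 10)
            got = levels.levels[i, j]
            assert (math.isnan(expected) and math.isnan(got)) or got == pytest.approx(expected)


# ---------------------------------------------------------------------------
# canonicalization


def _one_gene_annotation(strand):
    return GenomeAnnotation(
        [
            TranscriptModel(
                gene_id="g1",
                transcript_id="g1.t1",
                chrom="chr1",
                strand=strand,
                exons=[(100, 200), (300, 400)],
            )
        ]
    )


def test_tc_in_minus_gene_is_canonical_minus_site():
    ann = _one_gene_annotation("-")
    site = canonicalize_variant("chr1", 150, "T", "C", annotation=ann)
    assert isinstance(site, EditingSite)
    assert site.strand == "-"
    assert (site.ref_base, site.ed_base) == ("A", "G")


def test_ag_in_minus_gene_rejected_as_antisense():
    ann = _one_gene_annotation("-")
    result = canonicalize_variant("chr1", 150, "A", "G", annotation=ann)
    assert isinstance(result, Rejection)
    assert "antisense" in result.reason
    kept = canonicalize_variant("chr1", 150, "A", "G", annotation=ann, allow_antisense=True)
    assert isinstance(kept, EditingSite) and kept.strand == "+"


def test_full_substitution_by_strand_policy_table():
    """All 12 substitutions x both gene strands: only sense A>G / T>C pass."""
    for gene_strand in ("+", "-"):
        ann = _one_gene_annotation(gene_strand)
        for ref, alt in itertools.permutations("ACGT", 2):
            result = canonicalize_variant("chr1", 150, ref, alt, annotation=ann)
            sense = ((ref, alt) == ("A", "G") and gene_strand == "+") or (
                (ref, alt) == ("T", "C") and gene_strand == "-"
            )
            if sense:
                assert isinstance(result, EditingSite)
                assert result.strand == gene_strand
            else:
                assert isinstance(result, Rejection)
                if (ref, alt) not in (("A", "G"), ("T", "C")):
                    assert result.reason == "not A-to-G under either strand"


def test_canonicalization_is_involution():
    """Canonicalizing an already-canonical site reproduces it."""
    for strand in "+-":
        site = EditingSite("chr2", 77, strand)
        again = canonicalize_variant(
            site.chrom, site.pos, site.genomic_ref, site.genomic_alt, strand_hint=site.strand
        )
        assert again == site


def test_non_snv_input_raises():
    with pytest.raises(ValueError):
        canonicalize_variant("chr1", 5, "AT", "G")
    with pytest.raises(ValueError):
        canonicalize_variant("chr1", 5, "A", "A")


# ---------------------------------------------------------------------------
# high-confidence filter


def test_filter_branches():
    nan = float("nan")
    levels = _level_matrix(
        [
            [0.02, 0.015, 0.0, nan],  # threshold branch
            [0.02, 0.005, 0.0, 0.0],  # only one sample >= 1% -> removed
            [0.005, 0.005, nan, nan],  # rescued by the known table
        ]
    )
    known = {("chr1", 30, "+")}
    retained, log = filter_high_confidence(levels, known)
    assert list(log["branch"]) == ["threshold", "removed", "known"]
    assert [s.pos for s in retained.sites] == [10, 30]
    assert retained.sites[1].is_known


def test_filter_matches_bruteforce_oracle(rng):
    """On small random matrices the filter agrees with an exhaustive
    re-derivation written independently of the main code path."""
    for _ in range(50):
        n_sites = int(rng.integers(1, 6))
        n_samples = int(rng.integers(1, 6))
        levels = rng.uniform(0, 0.05, size=(n_sites, n_samples))
        levels[rng.random(size=levels.shape) < 0.3] = np.nan
        known_flags = rng.random(n_sites) < 0.3
        matrix = _level_matrix(levels)
        known = {("chr1", 10 * (i + 1), "+") for i in range(n_sites) if known_flags[i]}
        _, log = filter_high_confidence(matrix, known, min_level=0.01, min_samples=2)
        expected = filter_decisions_bruteforce(levels, known_flags, 0.01, 2)
        assert list(log["retained"]) == expected


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    data=st.data(),
    min_level=st.floats(0.005, 0.05),
    min_samples=st.integers(1, 4),
)
def test_filter_monotonicity(data, min_level, min_samples):
    """Raising min_level or min_samples never retains more sites; growing
    the known table never retains fewer."""
    n_sites = data.draw(st.integers(1, 8))
    n_samples = data.draw(st.integers(1, 6))
    raw = data.draw(
        st.lists(
            st.lists(
                st.one_of(st.just(float("nan")), st.floats(0, 0.08)),
                min_size=n_samples, max_size=n_samples,
            ),
            min_size=n_sites, max_size=n_sites,
        )
    )
    matrix = _level_matrix(raw)
    known = {("chr1", 10, "+")}
    n_base = len(filter_high_confidence(matrix, set(), min_level, min_samples)[0].sites)
    n_stricter_level = len(
        filter_high_confidence(matrix, set(), min_level + 0.01, min_samples)[0].sites
    )
    n_stricter_count = len(
        filter_high_confidence(matrix, set(), min_level, min_samples + 1)[0].sites
    )
    n_with_known = len(filter_high_confidence(matrix, known, min_level, min_samples)[0].sites)
    assert n_stricter_level <= n_base
    assert n_stricter_count <= n_base
    assert n_with_known >= n_base


# ---------------------------------------------------------------------------
# per-group accounting


def _metadata(samples, split):
    return pd.DataFrame(
        {"sample": samples, "group": ["case"] * split + ["control"] * (len(samples) - split)}
    )


def test_venn_partition_sums_to_total(rng):
    levels = rng.uniform(0, 0.05, size=(40, 8))
    levels[rng.random(size=levels.shape) < 0.4] = np.nan
    matrix = _level_matrix(levels)
    md = _metadata(matrix.samples, 4)
    acc = group_site_accounting(matrix, md)
    venn = acc["venn"]
    assert sum(venn.values()) == acc["total_sites"] == 40


def test_shared_site_counted_once():
    levels = _level_matrix([[0.5, 0.5], [0.5, 0.0], [0.0, 0.5], [0.0, 0.0]])
    md = _metadata(levels.samples, 1)
    acc = group_site_accounting(levels, md)
    assert acc["venn"] == {
        "case_exclusive": 1, "control_exclusive": 1, "shared": 1, "neither": 1
    }


def test_empty_group_rejected():
    levels = _level_matrix([[0.5, 0.5]])
    md = pd.DataFrame({"sample": ["s0", "sX"], "group": ["case", "control"]})
    with pytest.raises(ValueError):
        group_site_accounting(levels, md)


def test_case_only_sites_become_case_exclusive():
    """Sites with control mean 0 and decent case editing appear
    case-exclusive at high coverage (truth-table comparison)."""
    from editscape.core import SiteCountMatrix

    rng = np.random.default_rng(5)
    n_exclusive, n_shared, n_samp = 10, 30, 12
    phi_case = np.vstack(
        [np.full((n_exclusive, n_samp), 0.3), np.full((n_shared, n_samp), 0.3)]
    )
    phi_ctrl = np.vstack(
        [np.zeros((n_exclusive, n_samp)), np.full((n_shared, n_samp), 0.3)]
    )
    phi = np.hstack([phi_case, phi_ctrl])
    cov = np.full(phi.shape, 500)
    ed = rng.binomial(cov, phi)
    counts = SiteCountMatrix(
        [EditingSite("chr1", 10 * (i + 1), "+") for i in range(n_exclusive + n_shared)],
        [f"s{j}" for j in range(2 * n_samp)],
        cov - ed,
        ed,
    )
    levels = compute_levels(counts)
    md = _metadata(levels.samples, n_samp)
    acc = group_site_accounting(levels, md)
    assert acc["venn"]["case_exclusive"] == n_exclusive
    assert acc["venn"]["shared"] == n_shared
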