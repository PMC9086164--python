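"""Generator correctness: determinism, annotation validity, planted truth."""

import numpy as np
import pytest
from scipy import stats

from editscape import io as esio
from editscape.core import revcomp
from editscape.genome import Genome
from editscape.simulate import (
    CapacityError,
    SimConfig,
    generate_reference,
    plant_editing_sites,
    simulate_counts,
    simulate_dataset,
)

TINY = dict(n_chroms=1, chrom_length=60_000, n_genes=8, n_sites=60,
            n_differential=5, n_cis=2, n_samples_per_group=3)


def test_reference_is_deterministic(tmp_path):
    cfg = SimConfig(seed=1, **TINY)
    paths = []
    for run in ("a", "b"):
        out = tmp_path / run
        simulate_dataset(SimConfig(seed=1, **TINY), out_dir=out)
        paths.append(out)
    for name in ("reference.fa", "annotation.gtf", "counts.vcf", "known_sites.tsv",
                 "gene_counts.tsv", "metadata.tsv", "truth_sites.tsv"):
        assert (paths[0] / name).read_bytes() == (paths[1] / name).read_bytes(), name


def test_zero_genes_yields_empty_annotation(tmp_path):
    cfg = SimConfig(seed=2, n_chroms=1, chrom_length=10_000, n_genes=0,
                    n_sites=0, n_differential=0, n_cis=0)
    genome, annotation = generate_reference(cfg)
    assert len(annotation) == 0
    path = tmp_path / "empty.gtf"
    esio.write_gtf(annotation, path)
    assert path.read_text().startswith("#")
    assert len(esio.read_gtf(path)) == 0


def test_emitted_cds_are_valid_orfs(tmp_path):
    """Re-parse the emitted GTF against the emitted FASTA: every CDS must
    be a codon multiple starting with ATG and ending with a stop."""
    cfg = SimConfig(seed=3, **TINY)
    out = tmp_path / "d"
    simulate_dataset(cfg, out_dir=out)
    genome = Genome.from_fasta(out / "reference.fa")
    annotation = esio.read_gtf(out / "annotation.gtf")
    n_coding = 0
    for t in annotation.transcripts:
        if not t.coding:
            continue
        n_coding += 1
        assert t.cds_length % 3 == 0
        cds_seq = "".join(
            genome.stranded_base(t.chrom, p, t.strand) for p in t.cds_positions()
        )
        assert cds_seq.startswith("ATG")
        assert cds_seq[-3:] in ("TAA", "TAG", "TGA")
        internal = [cds_seq[i : i + 3] for i in range(3, len(cds_seq) - 3, 3)]
        assert not any(c in ("TAA", "TAG", "TGA") for c in internal)
    assert n_coding >= 1


def test_capacity_error_when_genome_too_small():
    cfg = SimConfig(seed=4, n_chroms=1, chrom_length=2_000, n_genes=10,
                    n_sites=0, n_differential=0, n_cis=0)
    with pytest.raises(CapacityError):
        generate_reference(cfg)


def test_too_many_sites_raises():
    cfg = SimConfig(seed=4, n_chroms=1, chrom_length=20_000, n_genes=2,
                    n_sites=8000, n_differential=0, n_cis=0)
    genome, annotation = generate_reference(cfg)
    with pytest.raises(CapacityError):
        plant_editing_sites(genome, annotation, cfg)


def test_planted_truth_is_consistent(small_data):
    """Strand-adjusted reference base at every site is A and the recorded
    13-mer matches the final reference."""
    genome = small_data.genome
    for row in small_data.truth.site_table.itertuples():
        assert genome.stranded_base(row.chrom, row.pos, row.strand) == "A"
        window = genome.fetch(row.chrom, row.pos - 6, row.pos + 6)
        if row.strand == "-":
            window = revcomp(window)
        assert window == row.context
        assert window[6] == "A"


def test_degenerate_motif_probability_forces_g():
    cfg = SimConfig(seed=5, motif_g_plus1_prob=1.0, motif_g_minus1_prob=0.0, **TINY)
    genome, annotation = generate_reference(cfg)
    truth = plant_editing_sites(genome, annotation, cfg)
    for ctx in truth.site_table["context"]:
        assert ctx[7] == "G"  # +1, strand-adjusted
        assert ctx[5] != "G"  # -1 never G


def test_minus1_g_depletion_detectable():
    """G frequency at -1 in the truth contexts is depleted relative to the
    ~25% background (binomial test on the emitted table)."""
    cfg = SimConfig(seed=6, n_chroms=1, chrom_length=400_000, n_genes=50,
                    n_sites=500, n_differential=0, n_cis=0, n_samples_per_group=3)
    genome, annotation = generate_reference(cfg)
    truth = plant_editing_sites(genome, annotation, cfg)
    g_at_minus1 = sum(ctx[5] == "G" for ctx in truth.site_table["context"])
    res = stats.binomtest(g_at_minus1, 500, 0.25, alternative="less")
    assert res.pvalue < 1e-6


def test_zero_shift_means_equal_group_means():
    cfg = SimConfig(seed=7, differential_shift=0.0, **TINY)
    genome, annotation = generate_reference(cfg)
    truth = plant_editing_sites(genome, annotation, cfg)
    assert np.allclose(truth.site_table["baseline_mean"], truth.site_table["case_mean"])


def test_counts_conserve_coverage_and_metadata_shape(small_data, small_config):
    counts = small_data.counts
    assert (counts.ref_counts + counts.ed_counts == counts.coverage).all()
    assert len(small_data.metadata) == 2 * small_config.n_samples_per_group
    assert set(small_data.metadata["group"]) == {"case", "control"}


def test_levels_concentrate_at_high_coverage():
    """With huge coverage and a fixed mid-range mean level, empirical
    G/(A+G) concentrates near the mean (law of large numbers)."""
    cfg = SimConfig(seed=8, coverage_mean=20_000.0, coverage_dispersion=50.0,
                    editing_alpha=5000.0, editing_beta=5000.0,
                    level_concentration=1e9,
                    **{**TINY, "n_differential": 0, "n_cis": 0})
    genome, annotation = generate_reference(cfg)
    truth = plant_editing_sites(genome, annotation, cfg)
    counts, _, _ = simulate_counts(truth, annotation, cfg)
    emp = counts.ed_counts / np.maximum(counts.coverage, 1)
    assert np.abs(emp - 0.5).max() < 0.05


def test_baseline_mean_matches_beta_prior():
    cfg = SimConfig(seed=9, n_chroms=1, chrom_length=600_000, n_genes=80,
                    n_sites=1500, n_differential=0, n_cis=0, n_samples_per_group=3)
    genome, annotation = generate_reference(cfg)
    truth = plant_editing_sites(genome, annotation, cfg)
    expected = cfg.editing_alpha / (cfg.editing_alpha + cfg.editing_beta)
    sd = np.sqrt(
        cfg.editing_alpha * cfg.editing_beta
        / ((cfg.editing_alpha + cfg.editing_beta) ** 2 * (cfg.editing_alpha + cfg.editing_beta + 1))
    )
    se = sd / np.sqrt(len(truth.site_table))
    assert abs(truth.site_table["baseline_mean"].mean() - expected) < 3 * se


def test_zero_cis_slope_decouples_expression(small_config):
    cfg = SimConfig(**{**small_config.__dict__, "cis_slope": 0.0, "seed": 10,
                       "category_weights": dict(small_config.category_weights)})
    data = simulate_dataset(cfg)
    truth = data.truth
    rhos = []
    for row in truth.site_table[truth.site_table["is_cis"]].itertuples():
        phi = truth.sample_levels.loc[row.site_id].to_numpy()
        expr = data.gene_counts.loc[row.gene_id].to_numpy(float)
        rho, _ = stats.spearmanr(phi, expr)
        rhos.append(rho)
    assert np.abs(np.mean(rhos)) < 0.5  # no systematic coupling


def test_known_fraction_zero_gives_decoy_only_table():
    cfg = SimConfig(seed=11, known_fraction=0.0, **TINY)
    data = simulate_dataset(cfg)
    assert len(data.known_table) == 0 or not set(
        zip(data.known_table["chrom"], data.known_table["pos"])
    ) & set(zip(data.truth.site_table["chrom"], data.truth.site_table["pos"]))


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(n_sites=5, n_differential=4, n_cis=2).validate()
    with pytest.raises(ValueError):
        SimConfig(motif_g_plus1_prob=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(differential_shift=1.0).validate()
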