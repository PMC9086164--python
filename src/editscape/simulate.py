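"""Synthetic dataset generator with planted ground truth.

Emulates the inputs of a brain A-to-I editing study: a small reference
genome with multi-exon gene models, a panel of editing sites planted at
strand-adjusted adenosines with an ADAR-like nearest-neighbour motif
(G depleted at -1, enriched at +1), per-sample base counts drawn from a
beta-binomial around group mean levels with negative-binomial coverage,
group effects at designated differential sites, gene expression coupled
to the editing level at designated cis-regulatory sites, a known-site
catalogue covering part of the panel plus decoys, and machine-readable
truth tables.

Every draw descends from ``SimConfig.seed``; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Faidx

from . import io as esio
from .core import EditingSite, GenomeAnnotation, SiteCountMatrix, TranscriptModel
from .genome import Genome

STOP_CODONS = ("TAA", "TAG", "TGA")
#: planted-site location mix, loosely shaped like the functional-category
#: spectrum reported for cortical editing panels (intron-dominated, 3'UTR
#: second, coding a few percent)
DEFAULT_CATEGORY_WEIGHTS = {
    "intron": 0.62,
    "utr3": 0.15,
    "cds": 0.07,
    "nc_intron": 0.07,
    "nc_exon": 0.04,
    "utr5": 0.02,
    "intergenic": 0.03,
}


class CapacityError(ValueError):
    """The configured genome cannot host the requested genes or sites."""


@dataclass
class SimConfig:
    """Study-design knobs for the generator.

    Defaults mirror the study scale where it is known (12 + 12 samples)
    and a desk-scale genome elsewhere: 2 chromosomes x 1 Mb, 300 genes,
    3000 sites of which 40 carry a group effect of +/-0.15 on the mean
    editing level and 6 are cis-coupled to their host gene's expression.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 300
    n_sites: int = 3000
    n_differential: int = 40
    n_cis: int = 6
    n_samples_per_group: int = 12
    coverage_mean: float = 50.0
    coverage_dispersion: float = 5.0
    editing_alpha: float = 2.0
    editing_beta: float = 8.0
    level_concentration: float = 50.0
    differential_shift: float = 0.15
    cis_slope: float = 4.0
    gene_mean: float = 200.0
    gene_dispersion: float = 10.0
    motif_g_minus1_prob: float = 0.05
    motif_g_plus1_prob: float = 0.6
    known_fraction: float = 0.5
    decoy_fraction: float = 0.1
    coding_fraction: float = 0.85
    category_weights: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS))

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 1000:
            raise ValueError("need at least one chromosome of >= 1 kb")
        if self.n_sites < 0 or self.n_genes < 0:
            raise ValueError("n_sites and n_genes must be non-negative")
        if self.n_differential + self.n_cis > self.n_sites:
            raise ValueError("n_differential + n_cis must not exceed n_sites")
        for name in (
            "motif_g_minus1_prob",
            "motif_g_plus1_prob",
            "known_fraction",
            "decoy_fraction",
            "coding_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not -1.0 < self.differential_shift < 1.0:
            raise ValueError("differential_shift must lie in (-1, 1)")
        for name in (
            "coverage_mean",
            "coverage_dispersion",
            "editing_alpha",
            "editing_beta",
            "level_concentration",
            "gene_mean",
            "gene_dispersion",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SimTruth:
    """Ground truth: per-site design and (after count simulation) the true
    per-sample editing levels."""

    config: SimConfig
    sites: list[EditingSite]
    site_table: pd.DataFrame
    sample_levels: pd.DataFrame | None = None  # sites x samples true phi

    def site_keys(self) -> list[tuple[str, int, str]]:
        return [s.key for s in self.sites]


# ---------------------------------------------------------------------------
# reference + annotation


def _make_transcript(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    slot_start: int,
    slot_end: int,
    coding: bool,
) -> tuple[TranscriptModel, dict]:
    """Lay out one transcript inside [slot_start, slot_end] (1-based)."""
    avail = slot_end - slot_start + 1
    if avail < 2 * 150 + 100 + 40:
        raise CapacityError(
            f"{gene_id}: slot of {avail} bp cannot host a two-exon transcript"
        )
    k = int(rng.integers(2, 5))
    exon_lens = rng.integers(150, 401, size=k)
    while exon_lens.sum() + 100 * (k - 1) + 40 > avail and k > 2:
        k -= 1
        exon_lens = rng.integers(150, 401, size=k)
    if exon_lens.sum() + 100 * (k - 1) + 40 > avail:
        exon_lens = np.full(2, 150)
        k = 2
    intron_budget = avail - 40 - int(exon_lens.sum())
    per_intron_max = intron_budget // (k - 1)
    if per_intron_max < 100:
        raise CapacityError(f"{gene_id}: no room for introns in a {avail} bp slot")
    intron_lens = rng.integers(100, min(1200, per_intron_max) + 1, size=k - 1)
    strand = "+" if rng.random() < 0.5 else "-"
    start = slot_start + int(rng.integers(0, avail - (exon_lens.sum() + intron_lens.sum()) + 1))
    exons = []
    cursor = start
    for i in range(k):
        exons.append((cursor, cursor + int(exon_lens[i]) - 1))
        cursor = exons[-1][1] + 1
        if i < k - 1:
            cursor += int(intron_lens[i])
    t_len = int(exon_lens.sum())

    layout = {"u5": None, "cds_len": None}
    cds_intervals: list[tuple[int, int]] = []
    if coding:
        u5 = int(rng.integers(20, 61))
        u3 = int(rng.integers(50, 151))
        cds_len = t_len - u5 - u3
        cds_len -= cds_len % 3
        if cds_len >= 60:
            layout = {"u5": u5, "cds_len": cds_len}
            # genomic CDS intervals from the transcript-order position map
            tpos = []
            ordered = exons if strand == "+" else exons[::-1]
            for s, e in ordered:
                seg = list(range(s, e + 1))
                tpos.extend(seg if strand == "+" else seg[::-1])
            cds_genomic = sorted(tpos[u5 : u5 + cds_len])
            runs = []
            run_start = prev = cds_genomic[0]
            for p in cds_genomic[1:]:
                if p != prev + 1:
                    runs.append((run_start, prev))
                    run_start = p
                prev = p
            runs.append((run_start, prev))
            cds_intervals = runs
    model = TranscriptModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=cds_intervals,
        gene_biotype="protein_coding" if cds_intervals else "lincRNA",
    )
    return model, layout


def _write_codons(genome: Genome, t: TranscriptModel, rng: np.random.Generator) -> None:
    """Force a valid ORF: ATG start, a stop at the end, no internal stops."""
    cds_pos = t.cds_positions()
    for i, b in enumerate("ATG"):
        genome.set_stranded_base(t.chrom, cds_pos[i], t.strand, b)
    stop = STOP_CODONS[int(rng.integers(0, 3))]
    for i, b in enumerate(stop):
        genome.set_stranded_base(t.chrom, cds_pos[-3 + i], t.strand, b)
    n_codons = len(cds_pos) // 3
    for c in range(1, n_codons - 1):
        codon = "".join(
            genome.stranded_base(t.chrom, cds_pos[3 * c + i], t.strand) for i in range(3)
        )
        if codon in STOP_CODONS:
            genome.set_stranded_base(t.chrom, cds_pos[3 * c], t.strand, "C")


def generate_reference(config: SimConfig) -> tuple[Genome, GenomeAnnotation]:
    """Random genome plus non-overlapping multi-exon gene models.

    Each coding transcript gets a forced valid ORF (ATG ... stop, length a
    multiple of 3, no internal stop codons) written into the sequence.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    seqs = {}
    for c in range(config.n_chroms):
        arr = rng.choice(list("ACGT"), size=config.chrom_length)
        seqs[f"chr{c + 1}"] = "".join(arr)
    genome = Genome(seqs)

    transcripts: list[TranscriptModel] = []
    if config.n_genes:
        per_chrom = [
            config.n_genes // config.n_chroms
            + (1 if c < config.n_genes % config.n_chroms else 0)
            for c in range(config.n_chroms)
        ]
        gid = 0
        for c, n_here in enumerate(per_chrom):
            if n_here == 0:
                continue
            chrom = f"chr{c + 1}"
            slot = config.chrom_length // n_here
            for g in range(n_here):
                gid += 1
                gene_id = f"g{gid:04d}"
                slot_start = g * slot + 30
                slot_end = (g + 1) * slot - 30
                coding = rng.random() < config.coding_fraction
                model, _ = _make_transcript(rng, gene_id, chrom, slot_start, slot_end, coding)
                if model.coding:
                    _write_codons(genome, model, rng)
                transcripts.append(model)
    return genome, GenomeAnnotation(transcripts)


# ---------------------------------------------------------------------------
# site planting


def _protected_positions(annotation: GenomeAnnotation) -> dict[str, set]:
    """Positions whose neighbourhood must not be rewritten (start/stop codons)."""
    protected: dict[str, set] = {}
    for t in annotation.transcripts:
        if not t.coding:
            continue
        cds_pos = t.cds_positions()
        guard = set(cds_pos[:3] + cds_pos[-3:])
        bucket = protected.setdefault(t.chrom, set())
        for p in guard:
            bucket.update((p - 1, p, p + 1))
    return protected


def _transcript_regions(t: TranscriptModel) -> dict[str, list[int]]:
    """Genomic positions by region type for one transcript."""
    regions: dict[str, list[int]] = {}
    intron_pos = []
    for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
        intron_pos.extend(range(e1 + 1, s2))
    if t.coding:
        tpos = t.exon_positions()
        cds_set = set(p for s, e in t.cds for p in range(s, e + 1))
        first = next(i for i, p in enumerate(tpos) if p in cds_set)
        last = len(tpos) - 1 - next(i for i, p in enumerate(reversed(tpos)) if p in cds_set)
        regions["utr5"] = tpos[:first]
        regions["utr3"] = tpos[last + 1 :]
        cds_ordered = t.cds_positions()
        regions["cds"] = cds_ordered[4:-4]  # keep clear of start/stop codons
        regions["intron"] = intron_pos
    else:
        regions["nc_exon"] = t.exon_positions()
        regions["nc_intron"] = intron_pos
    return regions


def plant_editing_sites(
    genome: Genome, annotation: GenomeAnnotation, config: SimConfig
) -> SimTruth:
    """Select editable adenosines, rewrite their -1/+1 neighbours per the
    motif probabilities, and assign per-site truth.

    The planted differential sites alternate the sign of the mean-level
    shift so both directions of change exist; cis sites get a random
    coupling sign. The recorded functional category is obtained by running
    the package's own annotator on the final (rewritten) reference, so the
    truth table and the pipeline share one definition of "category".
    """
    from .annotation import annotate_site

    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    flank_margin = 8
    protected = _protected_positions(annotation)

    pools: dict[str, list] = {k: [] for k in DEFAULT_CATEGORY_WEIGHTS}
    for t in annotation.transcripts:
        want = "A" if t.strand == "+" else "T"
        guard = protected.get(t.chrom, set())
        for bucket, positions in _transcript_regions(t).items():
            for p in positions:
                if p <= flank_margin or p > genome.length(t.chrom) - flank_margin:
                    continue
                if genome.base(t.chrom, p) != want:
                    continue
                if {p - 1, p, p + 1} & guard:
                    continue
                pools[bucket].append((t.chrom, p, t.strand, t.gene_id, t.transcript_id))

    # intergenic: outside every gene span, plus strand
    for chrom in genome.chroms:
        in_gene = np.zeros(genome.length(chrom) + 2, dtype=bool)
        for t in annotation.transcripts:
            if t.chrom == chrom:
                in_gene[t.start : t.end + 1] = True
        seq = np.array(list(genome.sequence(chrom)))
        candidates = np.flatnonzero(seq == "A") + 1
        for p in candidates:
            p = int(p)
            if p <= flank_margin or p > genome.length(chrom) - flank_margin:
                continue
            if in_gene[p]:
                continue
            pools["intergenic"].append((chrom, p, "+", None, None))

    weights = config.category_weights
    buckets = list(DEFAULT_CATEGORY_WEIGHTS)
    w = np.array([weights.get(b, 0.0) for b in buckets], dtype=float)
    if w.sum() <= 0:
        raise ValueError("category_weights must have positive mass")
    w = w / w.sum()
    wanted = rng.multinomial(config.n_sites, w)

    chosen: list[tuple] = []
    occupied: dict[str, set] = {}

    def take_from(bucket: str, n_want: int) -> int:
        pool = pools[bucket]
        taken = 0
        for idx in rng.permutation(len(pool)):
            if taken >= n_want:
                break
            chrom, p, strand, gene_id, tx_id = pool[idx]
            occ = occupied.setdefault(chrom, set())
            if {p - 1, p, p + 1} & occ:
                continue
            occ.update((p - 1, p, p + 1))
            chosen.append((chrom, p, strand, gene_id, tx_id, bucket))
            taken += 1
        return taken

    shortfall = 0
    for bucket, n_want in zip(buckets, wanted):
        shortfall += int(n_want) - take_from(bucket, int(n_want))
    if shortfall:  # spill unplaceable quota into introns, then anywhere
        shortfall -= take_from("intron", shortfall)
        for bucket in buckets:
            if shortfall <= 0:
                break
            shortfall -= take_from(bucket, shortfall)
    if len(chosen) < config.n_sites:
        raise CapacityError(
            f"only {len(chosen)} eligible A positions for {config.n_sites} requested sites"
        )

    chosen.sort(key=lambda r: (r[0], r[1]))

    # motif rewrite at strand-adjusted -1/+1
    for chrom, p, strand, *_ in chosen:
        up = p - 1 if strand == "+" else p + 1
        down = p + 1 if strand == "+" else p - 1
        for gpos, gprob in ((up, config.motif_g_minus1_prob), (down, config.motif_g_plus1_prob)):
            if rng.random() < gprob:
                genome.set_stranded_base(chrom, gpos, strand, "G")
            else:
                genome.set_stranded_base(
                    chrom, gpos, strand, "ACT"[int(rng.integers(0, 3))]
                )

    n = len(chosen)
    baseline = rng.beta(config.editing_alpha, config.editing_beta, size=n)
    case_mean = baseline.copy()
    shifts = np.zeros(n)

    # cis sites live in distinct host genes so each gene's expression is
    # coupled to exactly one site
    gene_hosted = [i for i, r in enumerate(chosen) if r[3] is not None]
    cis_idx: list[int] = []
    used_genes: set = set()
    for i in rng.permutation(gene_hosted):
        if len(cis_idx) >= config.n_cis:
            break
        gene = chosen[i][3]
        if gene in used_genes:
            continue
        used_genes.add(gene)
        cis_idx.append(int(i))
    if len(cis_idx) < config.n_cis:
        raise CapacityError("not enough gene-hosted sites for the requested cis sites")
    remaining = [i for i in rng.permutation(n) if i not in set(cis_idx)]
    diff_idx = remaining[: config.n_differential]
    if len(diff_idx) < config.n_differential:
        raise CapacityError("not enough sites for the requested differential sites")
    for k, i in enumerate(diff_idx):
        sign = 1.0 if k % 2 == 0 else -1.0
        shifts[i] = sign * config.differential_shift
        case_mean[i] = float(np.clip(baseline[i] + shifts[i], 0.0, 1.0))
    cis_sign = np.zeros(n, dtype=int)
    for i in cis_idx:
        cis_sign[i] = 1 if rng.random() < 0.5 else -1

    is_known = rng.random(n) < config.known_fraction

    sites = [EditingSite(c, p, s) for c, p, s, *_ in chosen]
    categories, contexts = [], []
    for site in sites:
        call = annotate_site(site, annotation, genome)
        categories.append(call.category)
        start, end = site.pos - 6, site.pos + 6
        ctx = genome.fetch(site.chrom, start, end)
        from .core import revcomp

        contexts.append(ctx if site.strand == "+" else revcomp(ctx))

    table = pd.DataFrame(
        {
            "site_id": [s.label() for s in sites],
            "chrom": [r[0] for r in chosen],
            "pos": [r[1] for r in chosen],
            "strand": [r[2] for r in chosen],
            "gene_id": [r[3] for r in chosen],
            "transcript_id": [r[4] for r in chosen],
            "bucket": [r[5] for r in chosen],
            "category": categories,
            "context": contexts,
            "baseline_mean": baseline,
            "case_mean": case_mean,
            "shift": shifts,
            "is_differential": [i in set(diff_idx) for i in range(n)],
            "is_cis": [i in set(cis_idx) for i in range(n)],
            "cis_sign": cis_sign,
            "is_known": is_known,
        }
    )
    return SimTruth(config=config, sites=sites, site_table=table)


# ---------------------------------------------------------------------------
# counts


def sample_names(config: SimConfig) -> tuple[list[str], pd.DataFrame]:
    case = [f"case_{i + 1:02d}" for i in range(config.n_samples_per_group)]
    ctrl = [f"control_{i + 1:02d}" for i in range(config.n_samples_per_group)]
    samples = case + ctrl
    metadata = pd.DataFrame(
        {"sample": samples, "group": ["case"] * len(case) + ["control"] * len(ctrl)}
    )
    return samples, metadata


def simulate_counts(
    truth: SimTruth, annotation: GenomeAnnotation, config: SimConfig
) -> tuple[SiteCountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw coverage, edited-read counts and gene expression counts.

    Coverage ~ NB(mean, dispersion); per-sample level phi ~ Beta around
    the group mean with concentration ``level_concentration``; edited
    reads ~ Binomial(coverage, phi). Gene counts ~ NB whose log-mean is
    shifted by cis_sign * cis_slope * (phi - overall mean level) at genes
    hosting a cis site. Fills ``truth.sample_levels`` as a side effect.
    """
    rng = np.random.default_rng([config.seed, 2])
    samples, metadata = sample_names(config)
    n_sites, n_samples = len(truth.sites), len(samples)
    is_case = np.array([g == "case" for g in metadata["group"]])

    mu = np.where(
        is_case[None, :],
        truth.site_table["case_mean"].to_numpy()[:, None],
        truth.site_table["baseline_mean"].to_numpy()[:, None],
    )
    kappa = config.level_concentration
    safe_mu = np.clip(mu, 1e-9, 1 - 1e-9)
    phi = rng.beta(safe_mu * kappa, (1 - safe_mu) * kappa, size=(n_sites, n_samples))
    phi = np.where(mu <= 0.0, 0.0, np.where(mu >= 1.0, 1.0, phi))

    d = config.coverage_dispersion
    p_nb = d / (d + config.coverage_mean)
    coverage = rng.negative_binomial(d, p_nb, size=(n_sites, n_samples))
    ed = rng.binomial(coverage, phi)
    counts = SiteCountMatrix(
        sites=list(truth.sites),
        samples=samples,
        ref_counts=coverage - ed,
        ed_counts=ed,
    )
    truth.sample_levels = pd.DataFrame(
        phi, index=truth.site_table["site_id"], columns=samples
    )

    genes = annotation.genes
    base = rng.lognormal(mean=np.log(config.gene_mean), sigma=1.0, size=len(genes))
    log_factor = np.zeros((len(genes), n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    overall_mean = config.editing_alpha / (config.editing_alpha + config.editing_beta)
    for i in np.flatnonzero(truth.site_table["is_cis"].to_numpy()):
        gene = truth.site_table["gene_id"].iloc[i]
        sign = int(truth.site_table["cis_sign"].iloc[i])
        gi = gene_index[gene]
        log_factor[gi] += sign * config.cis_slope * (phi[i] - overall_mean)
    mu_gene = base[:, None] * np.exp(log_factor)
    gd = config.gene_dispersion
    gene_counts = rng.negative_binomial(gd, gd / (gd + mu_gene))
    gene_df = pd.DataFrame(gene_counts, index=genes, columns=samples)
    return counts, gene_df, metadata


def build_known_table(
    truth: SimTruth, genome: Genome, config: SimConfig
) -> pd.DataFrame:
    """Known-site catalogue: the planted sites flagged known, plus decoy
    adenosines never edited (default ~10% of the table)."""
    rng = np.random.default_rng([config.seed, 3])
    known = truth.site_table[truth.site_table["is_known"]]
    rows = [
        {"chrom": r.chrom, "pos": int(r.pos), "ref": "A", "ed": "G", "strand": r.strand}
        for r in known.itertuples()
    ]
    planted = set(zip(truth.site_table["chrom"], truth.site_table["pos"]))
    if config.decoy_fraction > 0:
        n_decoys = int(round(len(rows) * config.decoy_fraction / (1 - config.decoy_fraction)))
        chroms = genome.chroms
        attempts = 0
        made = 0
        while made < n_decoys and attempts < 100 * max(n_decoys, 1):
            attempts += 1
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(8, genome.length(chrom) - 8)) + 1
            if (chrom, pos) in planted or genome.base(chrom, pos) != "A":
                continue
            planted.add((chrom, pos))
            rows.append({"chrom": chrom, "pos": pos, "ref": "A", "ed": "G", "strand": "+"})
            made += 1
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "ed", "strand"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimData:
    config: SimConfig
    genome: Genome
    annotation: GenomeAnnotation
    truth: SimTruth
    counts: SiteCountMatrix
    gene_counts: pd.DataFrame
    metadata: pd.DataFrame
    known_table: pd.DataFrame


def simulate_dataset(config: SimConfig, out_dir: str | Path | None = None) -> SimData:
    """Run every generator stage; optionally write the dataset to disk."""
    genome, annotation = generate_reference(config)
    truth = plant_editing_sites(genome, annotation, config)
    counts, gene_counts, metadata = simulate_counts(truth, annotation, config)
    known = build_known_table(truth, genome, config)
    data = SimData(config, genome, annotation, truth, counts, gene_counts, metadata, known)
    if out_dir is not None:
        write_dataset(data, out_dir)
    return data


def write_dataset(data: SimData, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["reference"] = out / "reference.fa"
    data.genome.to_fasta(paths["reference"])
    Faidx(str(paths["reference"]))  # build .fai alongside

    paths["annotation"] = out / "annotation.gtf"
    esio.write_gtf(data.annotation, paths["annotation"])

    paths["counts_dir"] = out / "counts"
    esio.write_counts_tsv(data.counts, paths["counts_dir"])
    paths["vcf"] = out / "counts.vcf"
    contig_lengths = {c: data.genome.length(c) for c in data.genome.chroms}
    esio.write_counts_vcf(data.counts, contig_lengths, paths["vcf"])

    paths["known_sites"] = out / "known_sites.tsv"
    esio.write_known_sites(data.known_table, paths["known_sites"])

    paths["gene_counts"] = out / "gene_counts.tsv"
    esio.write_gene_counts(data.gene_counts, paths["gene_counts"])

    paths["metadata"] = out / "metadata.tsv"
    esio.write_metadata(data.metadata, paths["metadata"])

    paths["truth_sites"] = out / "truth_sites.tsv"
    data.truth.site_table.to_csv(paths["truth_sites"], sep="\t", index=False)
    paths["truth_levels"] = out / "truth_levels.tsv"
    assert data.truth.sample_levels is not None
    data.truth.sample_levels.round(6).to_csv(paths["truth_levels"], sep="\t")

    paths["config"] = out / "sim_config.yaml"
    data.config.to_yaml(paths["config"])
    return paths
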