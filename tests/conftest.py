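import numpy as np
import pytest

from editscape.core import GenomeAnnotation, TranscriptModel
from editscape.genome import Genome
from editscape.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=7,
        n_chroms=1,
        chrom_length=150_000,
        n_genes=24,
        n_sites=250,
        n_differential=12,
        n_cis=3,
        n_samples_per_group=6,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("smalldata")
    simulate_dataset(small_config, out_dir=out)
    return out


def _toy_cds_codons():
    # ATG, AAA (Lys; pos-2 edit -> AGA Arg), GCA (Ala; pos-3 edit -> GCG Ala,
    # synonymous), TGG, CAT, TAG (stop; pos-2 edit -> TGG, stop lost)
    return ["ATG", "AAA", "GCA", "TGG", "CAT", "TAG"]


@pytest.fixture(scope="session")
def toy_gene():
    """Hand-built plus-strand two-exon coding gene with known codons.

    Layout on a 120 bp chromosome 'toy':
      exon1 11-40  (5'UTR 11-20, CDS part 1 21-30)
      intron 41-60 (position 50 holds an A)
      exon2 61-100 (CDS part 2 61-68, 3'UTR 69-100)
    The 18 bp CDS spells ATG AAA GCA TGG CAT TAG.
    """
    codons = _toy_cds_codons()
    cds_seq = "".join(codons)  # 18 bp
    seq = list("C" * 120)
    # 5'UTR content, an intronic A at 50, and 3'UTR content
    for i, b in enumerate(cds_seq[:10]):
        seq[20 + i] = b  # CDS part 1: 21-30
    for i, b in enumerate(cds_seq[10:]):
        seq[60 + i] = b  # CDS part 2: 61-68
    seq[49] = "A"  # intron
    seq[15] = "A"  # 5'UTR
    seq[79] = "A"  # 3'UTR
    genome = Genome({"toy": "".join(seq)})
    model = TranscriptModel(
        gene_id="toygene",
        transcript_id="toygene.t1",
        chrom="toy",
        strand="+",
        exons=[(11, 40), (61, 100)],
        cds=[(21, 30), (61, 68)],
    )
    return genome, GenomeAnnotation([model])


def mirror_annotation(genome: Genome, annotation: GenomeAnnotation):
    """Reverse-complement the genome and remap all features; used to check
    strand symmetry of consequence calls."""
    lengths = {c: genome.length(c) for c in genome.chroms}
    g2 = genome.reverse_complement()
    flipped = []
    for t in annotation.transcripts:
        L = lengths[t.chrom]
        flipped.append(
            TranscriptModel(
                gene_id=t.gene_id,
                transcript_id=t.transcript_id,
                chrom=t.chrom,
                strand="-" if t.strand == "+" else "+",
                exons=[(L - e + 1, L - s + 1) for s, e in t.exons],
                cds=[(L - e + 1, L - s + 1) for s, e in t.cds],
                gene_biotype=t.gene_biotype,
            )
        )
    return g2, GenomeAnnotation(flipped), lengths


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
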