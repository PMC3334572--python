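import numpy as np
import pytest

from fsindel.genome_model import (
    ConservationTrack,
    Indel,
    ProteinConservationTrack,
    TranscriptModel,
)


@pytest.fixture
def single_exon_tx():
    """+ strand, one exon [100,700), fully coding: 600 bp CDS."""
    return TranscriptModel(
        transcript_id="tx1", gene_id="g1", chrom="chr1", strand="+",
        exons=[(100, 700)], cds_start=100, cds_end=700,
    )


@pytest.fixture
def two_exon_tx():
    """+ strand, exons [100,200)+[300,500), CDS spans both: 300 bp."""
    return TranscriptModel(
        transcript_id="tx2", gene_id="g1", chrom="chr1", strand="+",
        exons=[(100, 200), (300, 500)], cds_start=100, cds_end=500,
    )


@pytest.fixture
def minus_tx():
    """- strand, single exon [100,200), fully coding."""
    return TranscriptModel(
        transcript_id="txm", gene_id="gm", chrom="chr1", strand="-",
        exons=[(100, 200)], cds_start=100, cds_end=200,
    )


def make_deletion(chrom, start, length, ind_id=None):
    """Deletion of `length` bp whose first deleted base is `start` (0-based)."""
    return Indel(chrom=chrom, pos=start - 1, ref_allele="A" + "C" * length,
                 alt_allele="A", id=ind_id)


def make_insertion(chrom, start, length, ind_id=None):
    """Insertion of `length` bp landing before `start` (0-based)."""
    return Indel(chrom=chrom, pos=start - 1, ref_allele="A",
                 alt_allele="A" + "C" * length, id=ind_id)


def random_transcript(rng, strand=None, chrom="chr1"):
    """Small random multi-exon transcript with a valid (3n) CDS."""
    n_exons = int(rng.integers(1, 5))
    n_codons = int(rng.integers(n_exons, 40))
    cuts = np.sort(rng.choice(np.arange(1, n_codons), size=n_exons - 1,
                              replace=False)) if n_exons > 1 else np.array([], int)
    sizes = np.diff(np.concatenate([[0], cuts * 3, [n_codons * 3]]))
    pos = int(rng.integers(50, 150))
    exons = []
    for s in sizes:
        exons.append((pos, pos + int(s)))
        pos += int(s) + int(rng.integers(20, 80))
    return TranscriptModel(
        transcript_id="rt", gene_id="rg", chrom=chrom,
        strand=strand or ("+" if rng.uniform() < 0.5 else "-"),
        exons=exons, cds_start=exons[0][0], cds_end=exons[-1][1],
    )
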