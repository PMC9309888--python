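"""Shared fixtures: a small hand-built genome/annotation and helpers."""

import numpy as np
import pytest

from plastedit import (
    Annotation,
    CircularSequence,
    GeneticCode,
    GenomeFeature,
)
from plastedit.pileup import Pileup, PileupColumn


@pytest.fixture(scope="session")
def code11():
    return GeneticCode.bacterial()


@pytest.fixture(scope="session")
def code_aua_met():
    return GeneticCode.bacterial_aua_met()


def make_column(position, ref, counts, phred=30.0, insertions=None):
    """Pileup column with one constant quality for every observed base."""
    quals = {b: phred for b, n in counts.items() if n > 0}
    return PileupColumn(position, ref, dict(counts), quals, insertions or [])


@pytest.fixture
def toy_genome():
    """300-bp genome: a + strand CDS, a - strand CDS, a tRNA, intergenic gaps.

    Layout (1-based):  CDS plus 11..70 (+), tRNA 81..110, CDS minus 121..180 (-).
    The CDS sequences are arbitrary but fixed; the plus CDS starts with ATG.
    """
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    seq = list("".join(rng.choice(bases, size=300)))
    seq[10:13] = "ATG"  # start of plus CDS
    genome = CircularSequence("toy", "".join(seq))
    ann = Annotation(
        "toy",
        [
            GenomeFeature("cds_plus", "CDS", [(11, 70)], "+", ["psbA"]),
            GenomeFeature("trna1", "tRNA", [(81, 110)], "+", ["trnF"]),
            GenomeFeature("cds_minus", "CDS", [(121, 180)], "-", ["rps2"]),
        ],
        sequence_length=300,
    )
    return genome, ann


def mirror_genome_annotation_pileup(genome, ann, pileup):
    """Reverse-complement the genome, flip strands, mirror the pileup."""
    from plastedit import reverse_complement

    length = genome.length
    mg = CircularSequence(genome.id, reverse_complement(genome.residues))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    feats = []
    for f in ann.features:
        segs = [(length + 1 - e, length + 1 - s) for s, e in f.segments]
        feats.append(
            GenomeFeature(
                f.feature_id,
                f.ftype,
                segs,
                "-" if f.strand == "+" else "+",
                list(f.gene_names),
                f.pseudo,
            )
        )
    mann = Annotation(ann.sequence_id, feats, sequence_length=length)
    mpile = Pileup(pileup.sequence_id)
    for col in pileup:
        counts = {comp[b]: n for b, n in col.counts.items()}
        quals = {comp[b]: q for b, q in col.mean_phred.items()}
        mpile.add(
            PileupColumn(length + 1 - col.position, comp[col.ref_base], counts, quals)
        )
    return mg, mann, mpile
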