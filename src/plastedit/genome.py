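"""Core domain types for circular plastid genomes.

Coordinates are 1-based inclusive everywhere at the interface, matching
GFF3/GenBank conventions.  A feature that crosses the origin of a circular
molecule is represented by two or more segments (GenBank ``join`` semantics),
never by ``start > end``.  Segments are stored in *sense* (transcription)
order: on the ``+`` strand each segment is walked ``start -> end``, on the
``-`` strand ``end -> start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CODING_TYPES = ("CDS", "tRNA", "rRNA")
FEATURE_TYPES = CODING_TYPES + ("intron", "repeat_region")

STOP = "*"


def _validate_dna(seq: str, allow_n: bool = True) -> str:
    """Uppercase ``seq`` and reject anything outside the DNA alphabet.

    ``U`` is rejected: the RNA alphabet appears only in edit-conversion
    labels, never in stored sequences.
    """
    seq = seq.upper()
    allowed = set(DNA_BASES) | ({"N"} if allow_n else set())
    for i, c in enumerate(seq):
        if c not in allowed:
            raise ValueError(f"non-DNA symbol {c!r} at position {i + 1}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed."""
    seq = _validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CircularSequence:
    """A (usually circular) DNA molecule."""

    id: str
    residues: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        self.residues = _validate_dna(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"interval {start}..{end} outside 1..{self.length}")
        return self.residues[start - 1 : end]


@dataclass
class GenomeFeature:
    """A strand-aware, possibly multi-segment (origin-wrapping) feature."""

    feature_id: str
    ftype: str
    segments: list[tuple[int, int]]
    strand: str
    gene_names: list[str] = field(default_factory=list)
    pseudo: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for start, end in self.segments:
            if start > end:
                raise ValueError(
                    f"segment {start}..{end} has start > end; origin-wrapping "
                    "features must be split into multiple segments"
                )

    def validate_coordinates(self, genome_length: int) -> None:
        for start, end in self.segments:
            if not (1 <= start and end <= genome_length):
                raise ValueError(
                    f"feature {self.feature_id}: segment {start}..{end} "
                    f"outside 1..{genome_length}"
                )

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.segments)

    def genomic_positions(self) -> list[int]:
        """Genome coordinates in sense (5'->3') order across segments."""
        out: list[int] = []
        for start, end in self.segments:
            if self.strand == "+":
                out.extend(range(start, end + 1))
            else:
                out.extend(range(end, start - 1, -1))
        return out

    def footprint(self) -> set[int]:
        """Unordered set of genome positions covered by the feature."""
        out: set[int] = set()
        for start, end in self.segments:
            out.update(range(start, end + 1))
        return out

    def contains(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.segments)

    def sense_sequence(self, genome: CircularSequence) -> str:
        """The feature's sequence on its own (sense) strand."""
        parts = [genome.fetch(s, e) for s, e in self.segments]
        if self.strand == "+":
            return "".join(parts)
        return "".join(reverse_complement(p) for p in parts)


@dataclass
class Annotation:
    """An ordered feature collection tied to one sequence."""

    sequence_id: str
    features: list[GenomeFeature] = field(default_factory=list)
    sequence_length: int | None = None
    is_circular: bool = True

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids: {dupes}")
        if self.sequence_length is not None:
            for f in self.features:
                f.validate_coordinates(self.sequence_length)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, feature_id: str) -> GenomeFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def coding_features(self) -> list[GenomeFeature]:
        return [f for f in self.features if f.ftype in CODING_TYPES]

    def features_at(self, position: int) -> list[GenomeFeature]:
        return [f for f in self.coding_features() if f.contains(position)]


@dataclass
class GeneticCode:
    """A 64-entry codon table (DNA codons; stop rendered as ``*``)."""

    code_id: str
    codon_to_aa: dict[str, str]
    variant_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"expected 64 codons, got {len(self.codon_to_aa)}")
        if STOP not in self.codon_to_aa.values():
            raise ValueError("code has no stop codon")

    @classmethod
    def bacterial(cls) -> "GeneticCode":
        """NCBI translation table 11 (bacterial/archaeal/plant plastid)."""
        table = CodonTable.unambiguous_dna_by_id[11]
        mapping = dict(table.forward_table)
        for codon in table.stop_codons:
            mapping[codon] = STOP
        return cls("table11", mapping)

    @classmethod
    def bacterial_aua_met(cls) -> "GeneticCode":
        """Table 11 with the deviant AUA=Met reassignment.

        The standard isoleucine codon AUA encodes methionine, as in the
        plastid genomes of green-plastid dinoflagellates.
        """
        base = cls.bacterial()
        mapping = dict(base.codon_to_aa)
        mapping["ATA"] = "M"
        return cls("table11+AUA=Met", mapping, {"AUA=Met"})


def translate(cds_sense_sequence: str, code: GeneticCode) -> str:
    """Translate a sense-strand CDS with the supplied code table.

    Stops are rendered as ``*``.  The input length must be divisible by 3.
    """
    seq = _validate_dna(cds_sense_sequence, allow_n=False)
    remainder = len(seq) % 3
    if remainder:
        raise ValueError(
            f"sequence length {len(seq)} not divisible by 3 (remainder {remainder})"
        )
    return "".join(code.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq), 3))


def feature_sense_position(
    feature: GenomeFeature, genome_position: int
) -> tuple[int, int | None, int | None]:
    """Map a genome coordinate to the feature's sense coordinates.

    Returns ``(sense_offset, codon_index, codon_position)`` with
    ``sense_offset`` counted 1-based from the feature's 5' end on its own
    strand, across segments in order.  Codon fields are ``None`` for
    non-CDS features.
    """
    positions = feature.genomic_positions()
    try:
        offset = positions.index(genome_position) + 1
    except ValueError:
        raise ValueError(
            f"position {genome_position} not inside feature {feature.feature_id}"
        ) from None
    if feature.ftype != "CDS":
        return offset, None, None
    codon_index = (offset + 2) // 3
    codon_position = ((offset - 1) % 3) + 1
    return offset, codon_index, codon_position
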