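"""RNA-editing detection and classification from RNA-vs-DNA pileups.

A site is called edited when an explicit two-model Phred posterior clears a
quality threshold (default 200) *and* the position lies inside a coding
feature (CDS/tRNA/rRNA).  Calls are classified strand-aware into the 12
base-conversion types (reported on the sense strand of the containing
gene, with DNA T rendered as RNA U) and into codon-position categories.

The quality model: with per-base error probability ``e_b = 10**(-Q_b/10)``,
model M0 says the transcript base equals the genome base (every mismatching
read is an error with probability ``e_b/3``); model M1 says the transcript
base is the most frequent non-reference base (every other read errs with
probability ``e/3`` of its own quality).  With equal priors the call
quality is ``-10*log10 P(M0 | data)``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

from .genome import (
    Annotation,
    CircularSequence,
    GeneticCode,
    GenomeFeature,
    STOP,
    feature_sense_position,
    reverse_complement,
    translate,
)
from .pileup import Pileup, PileupColumn

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}

#: the 12 conversion types, in conventional table order
CONVERSIONS = (
    "A>U", "A>G", "A>C",
    "U>A", "U>G", "U>C",
    "G>A", "G>U", "G>C",
    "C>A", "C>U", "C>G",
)

CATEGORIES = (1, 2, 3, "overlap", "structural_rna")

DEFAULT_QUAL_THRESHOLD = 200.0

_LN10 = math.log(10.0)


@dataclass
class EditSite:
    position: int
    feature_ids: list[str]
    from_base: str
    to_base: str
    conversion: str
    qual: float
    edited_fraction: float
    codon_category: int | str

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError("from_base equals to_base")
        if self.conversion != f"{self.from_base}>{self.to_base}":
            raise ValueError(
                f"conversion {self.conversion} inconsistent with "
                f"{self.from_base}>{self.to_base}"
            )


@dataclass
class InsertionEdit:
    anchor_position: int
    inserted_seq: str
    support: int
    support_fraction: float
    frame_restored: bool | None


@dataclass
class EditingSummary:
    per_type_counts: dict[str, int]
    total: int
    per_category_counts: dict[int | str, int]
    percent_of_coding_sites: float = field(default=float("nan"))


# ------------------------------------------------------------ quality model

def call_quality(column: PileupColumn, alt_base: str) -> float:
    """Phred-scaled posterior quality of the edited model at one column.

    ``-10*log10 P(M0 | data)`` with equal model priors; see module
    docstring for M0/M1.
    """
    ref = column.ref_base
    log10_l0 = 0.0
    log10_l1 = 0.0
    for b in "ACGT":
        n = column.counts[b]
        if n == 0:
            continue
        e = 10.0 ** (-column.mean_phred[b] / 10.0)
        log10_l0 += n * (math.log10(1.0 - e) if b == ref else math.log10(e / 3.0))
        log10_l1 += n * (
            math.log10(1.0 - e) if b == alt_base else math.log10(e / 3.0)
        )
    d = log10_l1 - log10_l0
    # qual = 10*log10(1 + 10**d), stable for large |d|
    return 10.0 * math.log1p(math.exp(min(d * _LN10, 700.0))) / _LN10 if d < 300 else 10.0 * d


def dominant_alt_base(column: PileupColumn) -> str | None:
    """Most frequent non-reference base (ties broken alphabetically)."""
    best, best_n = None, 0
    for b in "ACGT":
        if b == column.ref_base:
            continue
        if column.counts[b] > best_n:
            best, best_n = b, column.counts[b]
    return best


# ------------------------------------------------------------ classification

def classify_conversion(
    genome_ref_base: str, rna_alt_base_plus_strand: str, feature: GenomeFeature
) -> tuple[str, str, str]:
    """Sense-strand conversion label for a plus-strand (ref, alt) pair.

    Returns ``(from_base, to_base, conversion)`` in RNA letters.  For a
    minus-strand feature both bases are complemented before labeling.
    """
    ref, alt = genome_ref_base, rna_alt_base_plus_strand
    if ref == alt:
        raise ValueError("reference equals alternative base")
    if feature.strand == "-":
        ref, alt = _COMP[ref], _COMP[alt]
    frm, to = _TO_RNA[ref], _TO_RNA[alt]
    return frm, to, f"{frm}>{to}"


def assign_codon_category(
    position: int, covering: list[GenomeFeature]
) -> int | str:
    """Codon-position category of an edit site.

    ``overlap`` if >= 2 CDS features cover the position; ``structural_rna``
    if only tRNA/rRNA features do; otherwise the codon position (1/2/3)
    within the single covering CDS (a CDS wins over a co-covering RNA gene).
    """
    if not covering:
        raise ValueError(f"position {position} covered by no coding feature")
    cds = [f for f in covering if f.ftype == "CDS"]
    if len(cds) >= 2:
        return "overlap"
    if not cds:
        return "structural_rna"
    _, _, codon_pos = feature_sense_position(cds[0], position)
    return codon_pos


def _sense_feature(covering: list[GenomeFeature]) -> GenomeFeature:
    # the feature whose strand defines the reported conversion: first CDS
    # in annotation order, else the first RNA gene
    for f in covering:
        if f.ftype == "CDS":
            return f
    return covering[0]


# ------------------------------------------------------------ calling

def call_base_conversions(
    pileup: Pileup,
    genome: CircularSequence,
    ann: Annotation,
    qual_threshold: float = DEFAULT_QUAL_THRESHOLD,
) -> list[EditSite]:
    """Call RNA-DNA differences from a pileup.

    A site is returned iff its call quality exceeds ``qual_threshold`` and
    the position lies inside at least one CDS/tRNA/rRNA feature.
    Zero-coverage positions are skipped; reference N is skipped with a log
    notice.
    """
    pileup.validate_against(genome.length)
    for f in ann.features:
        f.validate_coordinates(genome.length)

    # position -> covering coding features, for featured positions only
    pos_index: dict[int, list[GenomeFeature]] = {}
    for f in ann.coding_features():
        for p in f.footprint():
            pos_index.setdefault(p, []).append(f)

    sites: list[EditSite] = []
    for column in pileup:
        if column.coverage == 0:
            continue
        if column.ref_base == "N":
            logger.info("skipping position %d: reference base N", column.position)
            continue
        covering = pos_index.get(column.position)
        if not covering:
            continue
        alt = dominant_alt_base(column)
        if alt is None:
            continue
        qual = call_quality(column, alt)
        if qual <= qual_threshold:
            continue
        feature = _sense_feature(covering)
        frm, to, conv = classify_conversion(column.ref_base, alt, feature)
        sites.append(
            EditSite(
                position=column.position,
                feature_ids=[f.feature_id for f in covering],
                from_base=frm,
                to_base=to,
                conversion=conv,
                qual=qual,
                edited_fraction=column.counts[alt] / column.coverage,
                codon_category=assign_codon_category(column.position, covering),
            )
        )
    return sites


# ------------------------------------------------------------ insertions

def detect_insertion_edits(
    pileup: Pileup,
    genome: CircularSequence,
    ann: Annotation,
    min_support: int = 10,
    min_fraction: float = 0.5,
) -> list[InsertionEdit]:
    """Detect base-insertion editing from pileup insertion observations.

    ``frame_restored`` is True iff splicing the insertion into the covering
    CDS makes its length divisible by 3 and removes all internal stops
    (evaluated with the bacterial+AUA=Met code).  An anchor outside any CDS
    is reported with ``frame_restored = None`` and a warning.
    """
    code = GeneticCode.bacterial_aua_met()
    out: list[InsertionEdit] = []
    for column in pileup:
        if not column.insertions:
            continue
        seq, support = max(column.insertions, key=lambda x: (x[1], x[0]))
        spanning = column.coverage
        if spanning == 0 or support < min_support:
            continue
        fraction = support / spanning
        if fraction < min_fraction:
            continue
        anchor = column.position
        cds = [
            f
            for f in ann.features
            if f.ftype == "CDS" and f.contains(anchor)
        ]
        if not cds:
            warnings.warn(
                f"insertion anchor {anchor} outside any CDS", stacklevel=2
            )
            out.append(InsertionEdit(anchor, seq, support, fraction, None))
            continue
        restored = _insertion_restores_frame(cds[0], anchor, seq, genome, code)
        out.append(InsertionEdit(anchor, seq, support, fraction, restored))
    return out


def _insertion_restores_frame(
    feature: GenomeFeature,
    anchor: int,
    inserted_seq: str,
    genome: CircularSequence,
    code: GeneticCode,
) -> bool:
    # splice the insertion (anchored after the plus-strand position) into
    # the plus-strand span, then read in the feature's sense
    start = min(s for s, _ in feature.segments)
    end = max(e for _, e in feature.segments)
    span = genome.fetch(start, end)
    offset = anchor - start + 1
    edited = span[:offset] + inserted_seq + span[offset:]
    if feature.strand == "-":
        edited = reverse_complement(edited)
    if len(edited) % 3 != 0:
        return False
    aa = translate(edited, code)
    return STOP not in aa[:-1]


# ------------------------------------------------------------ summaries

def summarize_editing(
    sites: list[EditSite], coding_site_count: int | None = None
) -> EditingSummary:
    """Aggregate called sites into per-type and per-category tables."""
    per_type = {c: 0 for c in CONVERSIONS}
    per_cat: dict[int | str, int] = {c: 0 for c in CATEGORIES}
    for s in sites:
        per_type[s.conversion] += 1
        per_cat[s.codon_category] += 1
    total = len(sites)
    if coding_site_count is None:
        return EditingSummary(per_type, total, per_cat)
    if coding_site_count <= 0:
        raise ValueError("coding_site_count must be positive")
    return EditingSummary(
        per_type, total, per_cat, 100.0 * total / coding_site_count
    )
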