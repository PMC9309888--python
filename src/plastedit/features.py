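"""Genome-compaction feature extraction for plastid genomes.

Computes the descriptive statistics used to compare green-plastid
dinoflagellate genomes with their free-living green-algal relatives:
GC content, intergenic fraction, inverted-repeat (IR) presence, ORF
overlap/fusion detection, pseudogene flagging, and evidence for the
deviant AUA=Met genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binomtest

from .genome import (
    Annotation,
    CircularSequence,
    GeneticCode,
    GenomeFeature,
    STOP,
    reverse_complement,
    translate,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "?"}

DEFAULT_MIN_ARM = 1000
DEFAULT_SEED_LENGTH = 20
DEFAULT_MAX_MISMATCH_FRACTION = 0.10


@dataclass
class InvertedRepeatPair:
    """Two disjoint genome intervals that are reverse complements.

    ``arm2``'s sequence equals ``reverse_complement`` of ``arm1``'s up to
    ``mismatches`` substitutions.  Intervals are 1-based inclusive and
    ``arm1`` is the lower-coordinate arm.
    """

    arm1: tuple[int, int]
    arm2: tuple[int, int]
    arm_length: int
    mismatches: int
    identity: float


@dataclass
class GenomeFeatureReport:
    genome_size: int
    gc_percent: float
    intergenic_percent: float
    n_functional_orfs: int
    n_rrna: int
    n_trna: int
    n_pseudogenes: int
    n_fusions: int
    n_overlap_pairs: int
    n_overlap_cds_cds: int
    n_overlap_cds_rna: int
    ir_present: bool


@dataclass
class AUAReport:
    n_aua: int
    n_at_met_columns: int
    n_at_ile_columns: int
    n_other: int
    verdict: str
    p_value: float


def gc_content(seq: CircularSequence | str) -> float:
    """GC percentage over A/C/G/T; N excluded from both terms."""
    residues = seq.residues if isinstance(seq, CircularSequence) else seq.upper()
    gc = residues.count("G") + residues.count("C")
    at = residues.count("A") + residues.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * gc / (gc + at)


def genic_positions(
    ann: Annotation, include_pseudo: bool = True, cds_only: bool = False
) -> set[int]:
    """Union of positions covered by coding features (counted once)."""
    out: set[int] = set()
    for f in ann.features:
        if f.ftype not in ("CDS", "tRNA", "rRNA"):
            continue
        if cds_only and f.ftype != "CDS":
            continue
        if not include_pseudo and f.pseudo:
            continue
        out |= f.footprint()
    return out


def coding_site_count(
    ann: Annotation,
    include_pseudo: bool = True,
    cds_only: bool = False,
    count_overlaps_twice: bool = False,
) -> int:
    """Number of coding positions, the denominator for editing percentages.

    Default: positions covered by >= 1 CDS/tRNA/rRNA, counted once even if
    covered by two overlapping features.  ``count_overlaps_twice`` sums
    feature lengths instead; ``cds_only`` restricts to CDS features.
    """
    if count_overlaps_twice:
        return sum(
            f.length
            for f in ann.features
            if f.ftype in (("CDS",) if cds_only else ("CDS", "tRNA", "rRNA"))
            and (include_pseudo or not f.pseudo)
        )
    return len(genic_positions(ann, include_pseudo, cds_only))


def intergenic_fraction(
    genome: CircularSequence, ann: Annotation, include_pseudo: bool = True
) -> float:
    """Percentage of the genome covered by no CDS/tRNA/rRNA feature.

    Overlapping features do not double-subtract.  Pseudogenes count as
    genic by default (they are annotated ORFs).
    """
    for f in ann.features:
        f.validate_coordinates(genome.length)
    covered = genic_positions(ann, include_pseudo=include_pseudo)
    return 100.0 * (genome.length - len(covered)) / genome.length


# ------------------------------------------------------------ inverted repeats

def _match_vector(seq: str, d: int, lo: int, hi: int) -> list[bool]:
    # seq[p] pairs with seq[d-p]; N never matches
    return [
        seq[p] != "N" and _COMP[seq[p]] == seq[d - p] for p in range(lo, hi + 1)
    ]


def find_inverted_repeats(
    genome: CircularSequence | str,
    min_arm: int = DEFAULT_MIN_ARM,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> list[InvertedRepeatPair]:
    """Seed-and-extend search for inverted repeats.

    Exact ``seed_length``-mers shared between the sequence and its reverse
    complement seed diagonals on which arms are extended, allowing
    substitutions up to ``max_mismatch_fraction`` of the arm length.  In
    exact mode (``max_mismatch_fraction == 0``) every maximal disjoint arm
    pair of length >= ``min_arm`` is reported; with mismatches allowed,
    overlapping hits are greedily merged (longest kept).  Results are
    sorted by arm length, descending.
    """
    seq = genome.residues if isinstance(genome, CircularSequence) else genome.upper()
    n = len(seq)
    if min_arm < seed_length:
        raise ValueError(f"min_arm ({min_arm}) < seed length ({seed_length})")
    k = seed_length

    # index of forward k-mers
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)

    # diagonals with at least one seed hit; a hit pairs arm1 start i with
    # arm2 end j+k-1, and along one extension the sum (arm1 pos + mirrored
    # arm2 pos) is constant: d = i + j + k - 1.
    diagonals: set[int] = set()
    for j in range(n - k + 1):
        rc = reverse_complement(seq[j : j + k])
        for i in index.get(rc, ()):
            if i + k - 1 < j:  # arm1 strictly before arm2
                diagonals.add(i + j + k - 1)

    pairs: list[InvertedRepeatPair] = []
    seen: set[tuple[int, int, int, int]] = set()
    for d in sorted(diagonals):
        lo = max(0, d - n + 1)
        hi = (d - 1) // 2  # p < d - p keeps the arms disjoint
        if hi - lo + 1 < min_arm:
            continue
        m = _match_vector(seq, d, lo, hi)
        if max_mismatch_fraction == 0:
            windows = _maximal_exact_runs(m, lo, min_arm)
        else:
            windows = _extend_with_mismatches(
                m, lo, min_arm, max_mismatch_fraction, k
            )
        for a, b, mm in windows:
            arm1 = (a + 1, b + 1)
            arm2 = (d - b + 1, d - a + 1)
            key = (*arm1, *arm2)
            if key in seen:
                continue
            seen.add(key)
            length = b - a + 1
            pairs.append(
                InvertedRepeatPair(arm1, arm2, length, mm, 1.0 - mm / length)
            )

    if max_mismatch_fraction > 0:
        pairs = _greedy_merge(pairs)
    pairs.sort(key=lambda p: (-p.arm_length, p.arm1))
    return pairs


def _maximal_exact_runs(m: list[bool], lo: int, min_arm: int):
    out = []
    i = 0
    while i < len(m):
        if m[i]:
            j = i
            while j + 1 < len(m) and m[j + 1]:
                j += 1
            if j - i + 1 >= min_arm:
                out.append((lo + i, lo + j, 0))
            i = j + 1
        else:
            i += 1
    return out


def _extend_with_mismatches(
    m: list[bool], lo: int, min_arm: int, max_frac: float, seed_len: int
):
    """X-drop extension of each exact seed run.

    Matches score +1, mismatches ``-(1/max_frac - 1)`` (neutral at exactly
    the allowed identity); extension stops once the running score drops a
    fixed amount below its maximum and the window is trimmed back to the
    best-scoring ends, so both ends are matches.  Windows violating the
    global mismatch budget are discarded.
    """
    penalty = 1.0 / max_frac - 1.0
    xdrop = 5.0 * penalty + 10.0
    prefix = [0]
    for v in m:
        prefix.append(prefix[-1] + (0 if v else 1))

    def mm(a, b):  # mismatches in window [a, b] (local indices)
        return prefix[b + 1] - prefix[a]

    def extend(start, step, limit):
        score = best_score = 0.0
        best = start
        p = start + step
        while 0 <= p < len(m) and (limit is None or p != limit):
            score += 1.0 if m[p] else -penalty
            if score > best_score:
                best_score, best = score, p
            if score < best_score - xdrop:
                break
            p += step
        return best

    out = []
    for sa, sb, _ in _maximal_exact_runs(m, lo, seed_len):
        a, b = sa - lo, sb - lo
        b = extend(b, +1, None)
        a = extend(a, -1, None)
        n_mm = mm(a, b)
        length = b - a + 1
        if length >= min_arm and n_mm <= max_frac * length:
            out.append((lo + a, lo + b, n_mm))
    # dedupe runs that converged to the same window
    return sorted(set(out))


def _overlaps(x: tuple[int, int], y: tuple[int, int]) -> bool:
    return x[0] <= y[1] and y[0] <= x[1]


def _greedy_merge(pairs: list[InvertedRepeatPair]) -> list[InvertedRepeatPair]:
    kept: list[InvertedRepeatPair] = []
    for p in sorted(pairs, key=lambda p: (-p.arm_length, p.arm1)):
        if any(
            _overlaps(p.arm1, q.arm1) and _overlaps(p.arm2, q.arm2) for q in kept
        ):
            continue
        kept.append(p)
    return kept


# ------------------------------------------------------------ overlaps/fusions

def detect_overlaps(ann: Annotation) -> list[tuple[str, str, int, str]]:
    """Unordered pairs of distinct coding features with intersecting footprints.

    ``kind`` distinguishes CDS-CDS from CDS-RNA (tRNA/rRNA) overlaps;
    origin-wrapping segments are handled through the footprint sets.
    """
    feats = [f for f in ann.features if f.ftype in ("CDS", "tRNA", "rRNA")]
    prints = [f.footprint() for f in feats]
    out = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            inter = prints[i] & prints[j]
            if not inter:
                continue
            types = {feats[i].ftype, feats[j].ftype}
            if types == {"CDS"}:
                kind = "CDS-CDS"
            elif "CDS" in types:
                kind = "CDS-RNA"
            else:
                kind = "RNA-RNA"
            out.append((feats[i].feature_id, feats[j].feature_id, len(inter), kind))
    return out


def detect_fusions(ann: Annotation) -> list[tuple[str, list[str]]]:
    """Features carrying >= 2 gene assignments, names in sense order."""
    out = []
    for f in ann.features:
        if len(f.gene_names) != len(set(f.gene_names)):
            raise ValueError(
                f"feature {f.feature_id} has duplicated gene names: {f.gene_names}"
            )
        if len(f.gene_names) > 1:
            out.append((f.feature_id, list(f.gene_names)))
    return out


# ------------------------------------------------------------ pseudogenes

def flag_pseudogene(
    feature: GenomeFeature, genome: CircularSequence, code: GeneticCode
) -> set[str]:
    """Advisory pseudogene flags for a CDS feature.

    ``frameshift_candidate``: the annotated span is not a multiple of 3, or
    the annotated frame hits a stop within the first 90% of codons while an
    alternative frame of the same span runs >= 20 codons past that stop.
    ``internal_stop``: a stop before the final codon (evaluated only when
    the frame is well defined, i.e. span % 3 == 0).
    """
    if feature.ftype != "CDS":
        raise ValueError("pseudogene flags apply to CDS features")
    sense = feature.sense_sequence(genome)
    if len(sense) < 6:
        raise ValueError(f"feature {feature.feature_id} shorter than 6 nt")
    if len(sense) % 3 != 0:
        return {"frameshift_candidate"}

    flags: set[str] = set()
    aa = translate(sense, code)
    first_stop = aa.find(STOP)
    if 0 <= first_stop < len(aa) - 1:
        flags.add("internal_stop")
        if first_stop < 0.9 * len(aa):
            for shift in (1, 2):
                alt = sense[shift:]
                alt = alt[: len(alt) - len(alt) % 3]
                alt_aa = translate(alt, code)
                # open stretch in the alternative frame that covers the stop
                # and continues at least 20 codons beyond it
                run_start = 0
                for i, r in enumerate(alt_aa + STOP):
                    if r == STOP:
                        if run_start <= first_stop and i - 1 >= first_stop + 20:
                            flags.add("frameshift_candidate")
                        run_start = i + 1
    if not flags:
        flags.add("clean")
    return flags


# ------------------------------------------------------------ AUA evidence

def aua_reassignment_evidence(
    query_codons: list[str],
    reference_aa_columns: list[list[str]],
    conservation_threshold: float = 2 / 3,
    alpha: float = 0.05,
) -> AUAReport:
    """Codon-capture style evidence for the AUA=Met reassignment.

    For every AUA codon of the query, the aligned reference residues decide
    whether the column is Met- or Ile-conserved (> ``conservation_threshold``
    of references agree).  A one-sided exact sign test (q = 0.5) over the
    informative columns decides the verdict.
    """
    if len(query_codons) != len(reference_aa_columns):
        raise ValueError(
            f"{len(query_codons)} codons but {len(reference_aa_columns)} "
            "reference columns"
        )
    n_met = n_ile = n_other = n_aua = 0
    for codon, refs in zip(query_codons, reference_aa_columns):
        if codon.upper().replace("U", "T") != "ATA":
            continue
        if len(refs) < 3:
            raise ValueError("need >= 3 reference residues per column")
        n_aua += 1
        refs = [r.upper() for r in refs]
        if refs.count("M") > conservation_threshold * len(refs):
            n_met += 1
        elif refs.count("I") > conservation_threshold * len(refs):
            n_ile += 1
        else:
            n_other += 1
    informative = n_met + n_ile
    if informative == 0:
        return AUAReport(n_aua, n_met, n_ile, n_other, "undetermined", 1.0)
    p = binomtest(max(n_met, n_ile), informative, 0.5, alternative="greater").pvalue
    if n_met > n_ile and p < alpha:
        verdict = "AUA=Met"
    elif n_ile > n_met and p < alpha:
        verdict = "AUA=Ile"
    else:
        verdict = "undetermined"
    return AUAReport(n_aua, n_met, n_ile, n_other, verdict, p)


# ------------------------------------------------------------ summary

def summarize_genome(
    genome: CircularSequence,
    ann: Annotation,
    min_arm: int = DEFAULT_MIN_ARM,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> GenomeFeatureReport:
    """One-row general-features report for a genome + annotation."""
    overlaps = detect_overlaps(ann)
    n_cds_cds = sum(1 for o in overlaps if o[3] == "CDS-CDS")
    n_cds_rna = sum(1 for o in overlaps if o[3] == "CDS-RNA")
    irs = find_inverted_repeats(
        genome,
        min_arm=min_arm,
        max_mismatch_fraction=max_mismatch_fraction,
        seed_length=seed_length,
    )
    return GenomeFeatureReport(
        genome_size=genome.length,
        gc_percent=gc_content(genome),
        intergenic_percent=intergenic_fraction(genome, ann),
        n_functional_orfs=sum(
            1 for f in ann.features if f.ftype == "CDS" and not f.pseudo
        ),
        n_rrna=sum(1 for f in ann.features if f.ftype == "rRNA"),
        n_trna=sum(1 for f in ann.features if f.ftype == "tRNA"),
        n_pseudogenes=sum(1 for f in ann.features if f.pseudo),
        n_fusions=len(detect_fusions(ann)),
        n_overlap_pairs=len(overlaps),
        n_overlap_cds_cds=n_cds_cds,
        n_overlap_cds_rna=n_cds_rna,
        ir_present=bool(irs),
    )


def compare_orf_repertoires(gene_sets: dict[str, set[str]]):
    """Presence/absence table of gene names across genomes (set comparison)."""
    import pandas as pd

    all_genes = sorted(set().union(*gene_sets.values()))
    return pd.DataFrame(
        {name: [g in s for g in all_genes] for name, s in gene_sets.items()},
        index=all_genes,
    )
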