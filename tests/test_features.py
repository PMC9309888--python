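"""Genome-compaction features: GC, intergenic, IRs, overlaps, pseudogenes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastedit import (
    Annotation,
    CircularSequence,
    GeneticCode,
    GenomeFeature,
    aua_reassignment_evidence,
    detect_fusions,
    detect_overlaps,
    find_inverted_repeats,
    flag_pseudogene,
    gc_content,
    intergenic_fraction,
    reverse_complement,
    summarize_genome,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# ------------------------------------------------------------ GC / intergenic

class TestGC:
    def test_examples(self):
        assert gc_content("GCGC") == 100.0
        assert gc_content("ATAT") == 0.0
        assert gc_content("ACGTN") == 50.0  # N excluded both sides

    def test_all_n_errors(self):
        with pytest.raises(ValueError):
            gc_content("NNN")

    @given(dna)
    @settings(max_examples=40, deadline=None)
    def test_reverse_complement_invariance(self, seq):
        assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))


class TestIntergenic:
    def test_empty_annotation_is_all_intergenic(self):
        g = CircularSequence("g", "ACGT" * 25)
        assert intergenic_fraction(g, Annotation("g", [])) == 100.0

    def test_full_coverage_and_half(self):
        g = CircularSequence("g", "A" * 1000)
        full = Annotation("g", [GenomeFeature("c", "CDS", [(1, 1000)], "+")])
        half = Annotation("g", [GenomeFeature("c", "CDS", [(1, 500)], "+")])
        assert intergenic_fraction(g, full) == 0.0
        assert intergenic_fraction(g, half) == 50.0

    def test_overlaps_do_not_double_subtract(self):
        g = CircularSequence("g", "A" * 1000)
        ann = Annotation(
            "g",
            [
                GenomeFeature("a", "CDS", [(1, 500)], "+"),
                GenomeFeature("b", "CDS", [(400, 600)], "+"),
            ],
        )
        assert intergenic_fraction(g, ann) == 40.0

    def test_split_feature_invariance(self):
        g = CircularSequence("g", "A" * 300)
        whole = Annotation("g", [GenomeFeature("a", "CDS", [(10, 99)], "+")])
        split = Annotation(
            "g",
            [
                GenomeFeature("a1", "CDS", [(10, 50)], "+"),
                GenomeFeature("a2", "CDS", [(51, 99)], "+"),
            ],
        )
        assert intergenic_fraction(g, whole) == intergenic_fraction(g, split)

    def test_out_of_range_errors(self):
        g = CircularSequence("g", "A" * 100)
        ann = Annotation("g", [GenomeFeature("a", "CDS", [(90, 120)], "+")])
        with pytest.raises(ValueError):
            intergenic_fraction(g, ann)


# ------------------------------------------------------------ inverted repeats

def brute_force_irs(seq, min_arm):
    """All maximal disjoint exact reverse-complement arm pairs (oracle).

    Enumerates every (start1, start2, length) triple and keeps the pairs
    that cannot be extended on either side.
    """
    n = len(seq)
    rc = reverse_complement(seq)

    def is_pair(s1, s2, L):  # 0-based starts
        if s1 + L > n or s2 + L > n or s1 + L > s2:
            return False
        return seq[s2 : s2 + L] == rc[n - s1 - L : n - s1]

    found = set()
    for L in range(min_arm, n + 1):
        for s1 in range(n - L + 1):
            for s2 in range(s1 + L, n - L + 1):
                if is_pair(s1, s2, L):
                    found.add((s1, s2, L))
    maximal = set()
    for s1, s2, L in found:
        if is_pair(s1 - 1, s2, L + 1) or is_pair(s1, s2 - 1, L + 1):
            continue
        maximal.add((s1 + 1, s1 + L, s2 + 1, s2 + L))
    return maximal


class TestInvertedRepeats:
    def test_planted_exact_arm(self):
        rng = np.random.default_rng(11)
        arm = random_seq(rng, 600)
        spacer = random_seq(rng, 50)
        genome = arm + spacer + reverse_complement(arm)
        pairs = find_inverted_repeats(genome, min_arm=600, max_mismatch_fraction=0)
        assert len(pairs) == 1
        (p,) = pairs
        assert p.arm_length == 600 and p.mismatches == 0
        assert p.arm1 == (1, 600) and p.arm2 == (651, 1250)

    def test_random_genome_has_no_long_ir(self):
        rng = np.random.default_rng(12)
        genome = random_seq(rng, 200)
        assert find_inverted_repeats(genome, min_arm=100, seed_length=20) == []

    def test_planted_arm_with_substitutions(self):
        rng = np.random.default_rng(13)
        arm = random_seq(rng, 500)
        arm2 = list(reverse_complement(arm))
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        # interior substitutions: edge clusters would be trimmed as locally
        # below-threshold extension, which is the intended behaviour
        sites = rng.choice(460, size=25, replace=False) + 20
        for i in sites:
            arm2[i] = swap[arm2[i]]
        # an all-A spacer cannot pair with itself, pinning the arm boundaries
        genome = arm + "A" * 60 + "".join(arm2)
        pairs = find_inverted_repeats(
            genome, min_arm=400, max_mismatch_fraction=0.1, seed_length=15
        )
        assert len(pairs) == 1
        assert pairs[0].mismatches == 25
        assert pairs[0].arm_length == 500
        assert pairs[0].arm1 == (1, 500) and pairs[0].arm2 == (561, 1060)

    def test_min_arm_below_seed_errors(self):
        with pytest.raises(ValueError, match="seed"):
            find_inverted_repeats("ACGT" * 100, min_arm=10, seed_length=20)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        for trial in range(10):
            n = int(rng.integers(60, 120))
            seq = random_seq(rng, n)
            if trial % 3 == 0:  # plant a short IR so hits actually occur
                arm = random_seq(rng, 12)
                seq = arm + seq + reverse_complement(arm)
            got = {
                (*p.arm1, *p.arm2)
                for p in find_inverted_repeats(
                    seq, min_arm=6, max_mismatch_fraction=0, seed_length=4
                )
            }
            assert got == brute_force_irs(seq, 6)


# ------------------------------------------------------------ overlaps/fusions

class TestOverlaps:
    def test_simple_overlap_length(self):
        ann = Annotation(
            "g",
            [
                GenomeFeature("a", "CDS", [(1, 300)], "+"),
                GenomeFeature("b", "CDS", [(250, 450)], "+"),
            ],
        )
        assert detect_overlaps(ann) == [("a", "b", 51, "CDS-CDS")]

    def test_disjoint_is_empty(self):
        ann = Annotation(
            "g",
            [
                GenomeFeature("a", "CDS", [(1, 100)], "+"),
                GenomeFeature("b", "CDS", [(101, 200)], "-"),
            ],
        )
        assert detect_overlaps(ann) == []

    def test_wrap_around_origin(self):
        ann = Annotation(
            "g",
            [
                GenomeFeature("a", "CDS", [(95, 100), (1, 10)], "+"),
                GenomeFeature("t", "tRNA", [(5, 8)], "+"),
            ],
            sequence_length=100,
        )
        assert detect_overlaps(ann) == [("a", "t", 4, "CDS-RNA")]

    def test_rotation_invariance(self):
        # overlap length unchanged when the circular origin is rotated
        base = [
            ("a", "CDS", [(10, 60)], "+"),
            ("b", "CDS", [(50, 90)], "+"),
        ]
        ann = Annotation("g", [GenomeFeature(*f) for f in base])
        ref = {(o[0], o[1], o[2]) for o in detect_overlaps(ann)}
        L, r = 100, 55

        def shift(p):
            return (p - r - 1) % L + 1

        rotated = []
        for fid, ft, segs, strand in base:
            (s, e) = segs[0]
            ns, ne = shift(s), shift(e)
            nsegs = [(ns, ne)] if ns <= ne else [(ns, L), (1, ne)]
            rotated.append(GenomeFeature(fid, ft, nsegs, strand))
        got = {(o[0], o[1], o[2]) for o in detect_overlaps(Annotation("g", rotated))}
        assert got == ref


class TestFusions:
    def test_two_gene_feature(self):
        ann = Annotation(
            "g", [GenomeFeature("f", "CDS", [(1, 99)], "+", ["psbK", "psaM"])]
        )
        assert detect_fusions(ann) == [("f", ["psbK", "psaM"])]

    def test_single_and_triple(self):
        ann = Annotation(
            "g",
            [
                GenomeFeature("s", "CDS", [(1, 30)], "+", ["rbcL"]),
                GenomeFeature("t", "CDS", [(40, 99)], "+", ["a", "b", "c"]),
            ],
        )
        assert detect_fusions(ann) == [("t", ["a", "b", "c"])]

    def test_duplicate_gene_name_errors(self):
        ann = Annotation(
            "g", [GenomeFeature("f", "CDS", [(1, 30)], "+", ["x", "x"])]
        )
        with pytest.raises(ValueError, match="duplicated"):
            detect_fusions(ann)


# ------------------------------------------------------------ pseudogenes

def orf_without_stops(rng, n_codons, code):
    stops = {"TAA", "TAG", "TGA"}
    codons = [c for c in code.codon_to_aa if c not in stops]
    body = "".join(rng.choice(codons) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


class TestPseudogeneFlags:
    def setup_method(self):
        self.rng = np.random.default_rng(21)
        self.code = GeneticCode.bacterial()

    def _genome_with(self, seq):
        g = CircularSequence("g", seq + "ACGT" * 10)
        f = GenomeFeature("f", "CDS", [(1, len(seq))], "+")
        return f, g

    def test_early_internal_stop_flagged(self):
        seq = orf_without_stops(self.rng, 100, self.code)
        seq = seq[:12] + "TAA" + seq[15:]  # stop at codon 5
        f, g = self._genome_with(seq)
        assert "internal_stop" in flag_pseudogene(f, g, self.code)

    def test_late_internal_stop_is_sole_flag(self):
        # a stop in the last 10% of codons cannot be a frameshift candidate
        seq = orf_without_stops(self.rng, 100, self.code)
        seq = seq[: 96 * 3] + "TAA" + seq[96 * 3 + 3 :]
        f, g = self._genome_with(seq)
        assert flag_pseudogene(f, g, self.code) == {"internal_stop"}

    def test_clean(self):
        seq = orf_without_stops(self.rng, 100, self.code)
        f, g = self._genome_with(seq)
        assert flag_pseudogene(f, g, self.code) == {"clean"}

    def test_one_nt_deletion_is_frameshift_candidate(self):
        seq = orf_without_stops(self.rng, 100, self.code)
        seq = seq[:90] + seq[91:]  # delete 1 nt at codon 30
        f, g = self._genome_with(seq)
        assert flag_pseudogene(f, g, self.code) == {"frameshift_candidate"}

    def test_too_short_errors(self):
        f, g = self._genome_with("ATGTA")
        f.segments = [(1, 5)]
        with pytest.raises(ValueError, match="6 nt"):
            flag_pseudogene(f, g, self.code)

    def test_clean_minus_strand_never_internal_stop(self):
        seq = orf_without_stops(self.rng, 60, self.code)
        g = CircularSequence("g", reverse_complement(seq) + "ACGT" * 5)
        f = GenomeFeature("f", "CDS", [(1, len(seq))], "-")
        assert "internal_stop" not in flag_pseudogene(f, g, self.code)


# ------------------------------------------------------------ AUA evidence

class TestAUAEvidence:
    def test_nine_met_one_ile(self):
        codons = ["ATA"] * 10
        refs = [["M"] * 6] * 9 + [["I"] * 6]
        rep = aua_reassignment_evidence(codons, refs)
        assert rep.verdict == "AUA=Met"
        assert rep.p_value == pytest.approx(11 / 1024)
        assert rep.n_aua == rep.n_at_met_columns + rep.n_at_ile_columns + rep.n_other

    def test_no_aua_is_undetermined(self):
        rep = aua_reassignment_evidence(["ATG", "AAA"], [["M"] * 3, ["K"] * 3])
        assert rep.verdict == "undetermined" and rep.n_aua == 0

    def test_balanced_is_undetermined(self):
        codons = ["ATA"] * 10
        refs = [["M"] * 6] * 5 + [["I"] * 6] * 5
        assert aua_reassignment_evidence(codons, refs).verdict == "undetermined"

    def test_misaligned_lengths_error(self):
        with pytest.raises(ValueError):
            aua_reassignment_evidence(["ATA"], [])


# ------------------------------------------------------------ summary

def test_summary_on_empty_annotation():
    rng = np.random.default_rng(31)
    g = CircularSequence("g", random_seq(rng, 1200))
    rep = summarize_genome(g, Annotation("g", []), min_arm=50)
    assert rep.intergenic_percent == 100.0
    assert rep.n_functional_orfs == rep.n_fusions == rep.n_overlap_pairs == 0
    assert not rep.ir_present


def test_summary_matches_simulator_truth():
    from plastedit import SimulationConfig, IRSpec, simulate_genome

    cfg = SimulationConfig(
        seed=5,
        genome_length=20000,
        n_orfs=12,
        n_overlap_pairs=2,
        n_fusions=1,
        n_pseudogenes=1,
        n_trna=3,
        n_rrna=2,
        ir=IRSpec(present=True, arm_length=400),
    )
    genome, ann, truth = simulate_genome(cfg)
    rep = summarize_genome(genome, ann, min_arm=300, seed_length=20)
    assert rep.genome_size == 20000
    assert rep.n_functional_orfs == 11  # one pseudogene excluded
    assert rep.n_pseudogenes == 1
    assert rep.n_fusions == 1
    assert rep.n_overlap_pairs == 2
    assert rep.n_trna == 3 and rep.n_rrna == 2
    assert rep.ir_present
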