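"""Seeded synthetic genomes, pileups and alignments with planted truth.

The generator emulates the data structure the analyses assume: a circular
plastid genome with overlapping/fused/pseudogenized ORFs and optional
inverted repeats; RNA pileups with planted base-conversion edits at chosen
coverage/quality plus one planted short insertion edit; and amino-acid
alignments evolved on the fixed 5-taxon tree with a category-specific
focal-branch rate multiplier.

RNG contract: one root seed; each component (genome, pileup, alignments)
draws from its own stream derived via ``numpy.random.SeedSequence.spawn``,
so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .genome import (
    Annotation,
    CircularSequence,
    GeneticCode,
    GenomeFeature,
    feature_sense_position,
)
from .pileup import Pileup, PileupColumn
from .phylo import MISSING, AA_ORDER, ProteinAlignment, SubstitutionModel, Tree5

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = ("TAA", "TAG", "TGA")
_DNA_OF_RNA = {"A": "A", "C": "C", "G": "G", "U": "T"}

#: plausible plastid gene names handed out to simulated ORFs
_GENE_POOL = [
    "psbA", "psbB", "psbC", "psbD", "psaA", "psaB", "psaC", "psbK", "psaM",
    "petA", "petB", "petD", "petG", "petL", "atpA", "atpB", "atpE", "atpH",
    "rps2", "rps3", "rps4", "rps7", "rps8", "rpl5", "rpl14", "rpl16",
    "rpl36", "rpoA", "rpoB", "rpoC1", "rbcL", "tufA", "ycf3", "clpP",
    "ccsA", "chlB", "chlL", "chlN", "psbE", "psbF",
]


@dataclass
class IRSpec:
    present: bool = False
    arm_length: int = 1000


@dataclass
class EditSpec:
    conversions: dict[str, int] = field(default_factory=dict)
    coverage: float = 50.0
    phred: float = 30.0
    per_base_error: float = 1e-3
    edited_fraction: float = 1.0


@dataclass
class InsertionSpec:
    length: int = 2  # the psaA-like two-nucleotide case
    support_fraction: float = 0.9


@dataclass
class AlignmentSpec:
    branch_lengths: tuple = (0.05, 0.05, 0.05, 0.05, 0.4, 0.03, 0.03)
    rate_multiplier: dict[str, float] = field(
        default_factory=lambda: {"photosynthetic": 1.0, "non_photosynthetic": 1.0}
    )
    n_proteins: dict[str, int] = field(
        default_factory=lambda: {"photosynthetic": 30, "non_photosynthetic": 20}
    )
    n_sites: int = 2000


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 20000
    gc_target: float = 34.8
    n_orfs: int = 20
    n_overlap_pairs: int = 2
    n_fusions: int = 1
    n_pseudogenes: int = 1
    n_trna: int = 4
    n_rrna: int = 2
    ir: IRSpec = field(default_factory=IRSpec)
    edit_spec: EditSpec = field(default_factory=EditSpec)
    insertion_spec: InsertionSpec | None = None
    alignment_spec: AlignmentSpec | None = None
    wrap_origin_orf: bool = False

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        raw = yaml.safe_load(open(path))
        for key, sub in (
            ("ir", IRSpec),
            ("edit_spec", EditSpec),
            ("alignment_spec", AlignmentSpec),
            ("insertion_spec", InsertionSpec),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Everything planted, for recovery tests."""

    edits: list[tuple[int, str, object]] = field(default_factory=list)
    insertion: tuple[int, str] | None = None
    ir_arms: tuple[tuple[int, int], tuple[int, int]] | None = None
    pseudogene_ids: list[str] = field(default_factory=list)
    fusion_ids: list[str] = field(default_factory=list)
    overlap_pairs: list[tuple[str, str]] = field(default_factory=list)
    broken_cds_id: str | None = None
    tree: Tree5 | None = None
    categories: dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        if self.tree is not None:
            d["tree"] = {
                "taxa": list(self.tree.taxa),
                "branch_lengths": [float(x) for x in self.tree.branch_lengths],
            }
        return d


def _streams(seed: int, n: int = 4):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ------------------------------------------------------------ genome

def _random_bases(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p)])


def _codon_probs(gc_adj: float) -> tuple[list[str], np.ndarray]:
    base_p = {
        "A": (1 - gc_adj) / 2,
        "C": gc_adj / 2,
        "G": gc_adj / 2,
        "T": (1 - gc_adj) / 2,
    }
    codons, probs = [], []
    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                codon = a + b + c
                if codon in _STOPS:
                    continue
                codons.append(codon)
                probs.append(base_p[a] * base_p[b] * base_p[c])
    probs = np.array(probs)
    return codons, probs / probs.sum()


def _solve_orf_gc(target: float) -> float:
    """Per-base GC such that stop-free codon sampling hits ``target`` GC."""

    def expected(g):
        codons, probs = _codon_probs(g)
        gc_frac = np.array([sum(c in "GC" for c in cod) / 3 for cod in codons])
        return float(probs @ gc_frac)

    lo, hi = 0.01, 0.99
    for _ in range(60):
        mid = (lo + hi) / 2
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _sample_orf(rng, n_codons: int, codons, probs) -> str:
    """Stop-free ORF: ATG + internal codons + one stop."""
    internal = rng.choice(len(codons), size=n_codons - 2, p=probs)
    stop = _STOPS[rng.integers(3)]
    return "ATG" + "".join(codons[i] for i in internal) + stop


def _has_internal_stop(seq: str) -> bool:
    trimmed = seq[: len(seq) - len(seq) % 3]
    return any(
        trimmed[i : i + 3] in _STOPS for i in range(0, len(trimmed) - 3, 3)
    )


def simulate_genome(
    cfg: SimulationConfig,
) -> tuple[CircularSequence, Annotation, GroundTruth]:
    """Seeded circular genome + annotation with the requested layout."""
    rng = _streams(cfg.seed)[0]
    gc = cfg.gc_target / 100.0
    gc_orf = _solve_orf_gc(gc)
    codons, cprobs = _codon_probs(gc_orf)
    truth = GroundTruth()

    if cfg.n_orfs < 2 * cfg.n_overlap_pairs + cfg.n_fusions + cfg.n_pseudogenes + (
        1 if cfg.insertion_spec else 0
    ):
        raise ValueError(
            "n_orfs too small for the requested overlap/fusion/pseudogene/"
            "insertion layout"
        )

    name_pool = list(_GENE_POOL)

    def take_name():
        return name_pool.pop(0) if name_pool else f"orf{rng.integers(100, 999)}"

    # blocks: (sequence, [(ftype, rel_segments, strand, names, pseudo, fid_hint)])
    blocks: list[tuple[str, list]] = []
    orf_counter = 0

    def next_fid(prefix):
        nonlocal orf_counter
        orf_counter += 1
        return f"{prefix}{orf_counter:03d}"

    # overlapping pairs: two same-strand ORFs on distinct frames, 20 nt shared
    overlap = 20
    for _ in range(cfg.n_overlap_pairs):
        for _attempt in range(500):
            l1 = int(rng.integers(100, 200)) * 3
            l2 = int(rng.integers(100, 200)) * 3
            orf1 = _sample_orf(rng, l1 // 3, codons, cprobs)
            tail = orf1[-overlap:]
            rest_len = l2 - overlap
            body = tail
            # complete the partial codon, then stop-free codons, then a stop
            while len(body) < l2 - 3:
                need = 3 - len(body) % 3 if len(body) % 3 else 3
                if need < 3:
                    frag = _random_bases(rng, need, gc_orf)
                    if body[len(body) - len(body) % 3 :] + frag in _STOPS:
                        continue
                    body += frag
                else:
                    body += codons[rng.choice(len(codons), p=cprobs)]
            body = body[: l2 - 3] + _STOPS[rng.integers(3)]
            if not _has_internal_stop(body) and not _has_internal_stop(orf1):
                break
        else:
            raise RuntimeError("could not build a clean overlapping ORF pair")
        merged = orf1 + body[overlap:]
        f1, f2 = next_fid("orf"), next_fid("orf")
        blocks.append(
            (
                merged,
                [
                    ("CDS", [(1, l1)], "+", [take_name()], False, f1),
                    ("CDS", [(l1 - overlap + 1, l1 - overlap + l2)], "+",
                     [take_name()], False, f2),
                ],
            )
        )
        truth.overlap_pairs.append((f1, f2))
        assert rest_len > 0

    n_singles = cfg.n_orfs - 2 * cfg.n_overlap_pairs
    specials = (
        ["fusion"] * cfg.n_fusions
        + ["pseudo"] * cfg.n_pseudogenes
        + (["broken"] if cfg.insertion_spec else [])
    )
    roles = specials + ["plain"] * (n_singles - len(specials))
    for role in roles:
        l = int(rng.integers(100, 300)) * 3
        seq = _sample_orf(rng, l // 3, codons, cprobs)
        strand = "+" if rng.random() < 0.5 else "-"
        fid = next_fid("orf")
        names = [take_name()]
        pseudo = False
        if role == "fusion":
            names.append(take_name())
            truth.fusion_ids.append(fid)
        elif role == "pseudo":
            # plant one internal stop mid-ORF
            mid = (l // 6) * 3
            seq = seq[:mid] + "TAA" + seq[mid + 3 :]
            pseudo = True
            truth.pseudogene_ids.append(fid)
        elif role == "broken":
            # remove a couple of nucleotides so the genomic frame is broken;
            # re-inserting them restores the reading frame (psaA-like)
            ins_len = cfg.insertion_spec.length
            cut = (l // 2) + 1
            removed = seq[cut : cut + ins_len]
            seq = seq[:cut] + seq[cut + ins_len :]
            l = len(seq)
            strand = "+"  # anchor bookkeeping kept simple on the plus strand
            truth.broken_cds_id = fid
            truth.insertion = (cut, removed)  # anchor relative to block start
        if strand == "-":
            seq = "".join(_COMP[c] for c in reversed(seq))
        blocks.append((seq, [("CDS", [(1, l)], strand, names, pseudo, fid)]))

    for i in range(cfg.n_trna):
        seq = _random_bases(rng, 72, gc)
        blocks.append((seq, [("tRNA", [(1, 72)], "+", [f"trn{chr(65 + i)}"],
                              False, f"trna{i + 1:02d}")]))
    for i in range(cfg.n_rrna):
        seq = _random_bases(rng, 1500, gc)
        blocks.append((seq, [("rRNA", [(1, 1500)], "+", ["rns" if i == 0 else "rnl"],
                              False, f"rrna{i + 1:02d}")]))

    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    ir_arm = None
    if cfg.ir.present:
        ir_arm = _random_bases(rng, cfg.ir.arm_length, gc)
        # arm1 after the first third of blocks, arm2 near the end
        k1 = max(1, len(blocks) // 3)
        blocks.insert(k1, (ir_arm, [("repeat_region",
                                     [(1, cfg.ir.arm_length)], "+", [], False, "ir_a")]))
        rc = "".join(_COMP[c] for c in reversed(ir_arm))
        blocks.append((rc, [("repeat_region", [(1, cfg.ir.arm_length)], "+",
                             [], False, "ir_b")]))

    total = sum(len(b[0]) for b in blocks)
    min_gap, max_gap = 50, 150
    need = total + (len(blocks) + 1) * min_gap
    if need > cfg.genome_length:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small: features plus "
            f"minimum spacers need {need} nt"
        )

    parts: list[str] = []
    features: list[GenomeFeature] = []
    pos = 0
    slack = cfg.genome_length - total - (len(blocks) + 1) * min_gap
    for seq, feats in blocks:
        gap = min_gap + int(rng.integers(0, max_gap - min_gap)) if slack > max_gap else min_gap
        gap = min(gap, min_gap + slack)
        slack -= gap - min_gap
        parts.append(_random_bases(rng, gap, gc))
        pos += gap
        for ftype, segs, strand, names, pseudo, fid in feats:
            features.append(
                GenomeFeature(
                    feature_id=fid,
                    ftype=ftype,
                    segments=[(pos + s, pos + e) for s, e in segs],
                    strand=strand,
                    gene_names=list(names),
                    pseudo=pseudo,
                )
            )
            if fid == truth.broken_cds_id and truth.insertion is not None:
                anchor, removed = truth.insertion
                truth.insertion = (pos + anchor, removed)
        parts.append(seq)
        pos += len(seq)
    tail = cfg.genome_length - pos
    parts.append(_random_bases(rng, tail, gc))
    residues = "".join(parts)
    assert len(residues) == cfg.genome_length

    if ir_arm is not None:
        a = next(f for f in features if f.feature_id == "ir_a").segments[0]
        b = next(f for f in features if f.feature_id == "ir_b").segments[0]
        truth.ir_arms = (a, b)

    genome = CircularSequence(f"sim{cfg.seed}", residues)
    ann = Annotation(genome.id, features, sequence_length=cfg.genome_length)

    if cfg.wrap_origin_orf:
        genome, ann, truth = _rotate(genome, ann, truth, features)

    return genome, ann, truth


def _rotate(genome, ann, truth, features):
    """Rotate the circular origin into the first CDS so it wraps."""
    first_cds = next(f for f in features if f.ftype == "CDS")
    s, e = first_cds.segments[0]
    r = (s + e) // 2  # new origin lands mid-feature
    length = genome.length
    residues = genome.residues[r:] + genome.residues[:r]

    def shift(p):
        return (p - r - 1) % length + 1

    new_feats = []
    for f in features:
        segs = []
        for a, b in f.segments:
            na, nb = shift(a), shift(b)
            if na <= nb:
                segs.append((na, nb))
            else:  # crosses the new origin: split, sense order preserved
                segs.extend([(na, length), (1, nb)])
        if f.strand == "-" and len(segs) > len(f.segments):
            # sense order for minus strand runs high->low coordinates
            segs = segs[::-1]
        new_feats.append(
            GenomeFeature(f.feature_id, f.ftype, segs, f.strand,
                          list(f.gene_names), f.pseudo, f.notes)
        )
    new_truth = truth
    if truth.insertion is not None:
        new_truth.insertion = (shift(truth.insertion[0]), truth.insertion[1])
    if truth.ir_arms is not None:
        new_truth.ir_arms = tuple(
            (shift(a), shift(b)) for a, b in truth.ir_arms
        )
    g = CircularSequence(genome.id, residues)
    return g, Annotation(genome.id, new_feats, sequence_length=length), new_truth


# ------------------------------------------------------------ pileup

def simulate_pileup(
    genome: CircularSequence,
    ann: Annotation,
    cfg: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[Pileup, GroundTruth]:
    """Poisson-coverage pileup with planted edits and constant qualities."""
    rng = _streams(cfg.seed)[1]
    spec = cfg.edit_spec
    truth = truth if truth is not None else GroundTruth()
    length = genome.length

    # eligible planting positions: covered by exactly one coding feature,
    # that feature a CDS (keeps the planted category unambiguous)
    cover: dict[int, list[GenomeFeature]] = {}
    for f in ann.coding_features():
        for p in f.footprint():
            cover.setdefault(p, []).append(f)
    by_sense_base: dict[str, list[tuple[int, GenomeFeature]]] = {
        b: [] for b in _BASES
    }
    for p, feats in sorted(cover.items()):
        if len(feats) != 1 or feats[0].ftype != "CDS":
            continue
        f = feats[0]
        plus_ref = genome.residues[p - 1]
        if plus_ref == "N":
            continue
        sense_ref = plus_ref if f.strand == "+" else _COMP[plus_ref]
        by_sense_base[sense_ref].append((p, f))

    alt_plus: dict[int, str] = {}
    for conv, count in spec.conversions.items():
        if count == 0:
            continue
        frm, to = conv.split(">")
        frm_dna, to_dna = _DNA_OF_RNA[frm], _DNA_OF_RNA[to]
        pool = [
            (p, f) for p, f in by_sense_base[frm_dna] if p not in alt_plus
        ]
        if len(pool) < count:
            raise ValueError(
                f"only {len(pool)} eligible positions for conversion {conv}, "
                f"need {count}"
            )
        picks = rng.choice(len(pool), size=count, replace=False)
        for i in picks:
            p, f = pool[i]
            alt = to_dna if f.strand == "+" else _COMP[to_dna]
            alt_plus[p] = alt
            _off, _ci, codon_pos = feature_sense_position(f, p)
            truth.edits.append((p, conv, codon_pos))

    base_idx = {b: i for i, b in enumerate(_BASES)}
    ref_codes = np.array([base_idx.get(c, -1) for c in genome.residues])
    eps = spec.per_base_error
    pvals = np.full((length, 4), eps / 3.0)
    valid = ref_codes >= 0
    pvals[np.arange(length)[valid], ref_codes[valid]] = 1.0 - eps
    for p, alt in alt_plus.items():
        row = np.full(4, (1.0 - spec.edited_fraction) * eps / 3.0)
        r = ref_codes[p - 1]
        row[r] = (1.0 - spec.edited_fraction) * (1.0 - eps)
        row[base_idx[alt]] += spec.edited_fraction
        pvals[p - 1] = row
    pvals /= pvals.sum(axis=1, keepdims=True)

    depth = rng.poisson(spec.coverage, size=length)
    counts = rng.multinomial(depth, pvals)

    pileup = Pileup(genome.id)
    ins_anchor = truth.insertion[0] if truth.insertion else None
    for p in range(1, length + 1):
        n = int(depth[p - 1])
        if n == 0 or ref_codes[p - 1] < 0:
            continue
        row = counts[p - 1]
        col_counts = {b: int(row[i]) for i, b in enumerate(_BASES)}
        quals = {b: spec.phred for b in _BASES if col_counts[b] > 0}
        insertions = []
        if (
            ins_anchor == p
            and cfg.insertion_spec is not None
            and truth.insertion is not None
        ):
            support = int(rng.binomial(n, cfg.insertion_spec.support_fraction))
            if support > 0:
                insertions.append((truth.insertion[1], support))
        pileup.add(PileupColumn(p, genome.residues[p - 1], col_counts, quals,
                                insertions))
    return pileup, truth


# ------------------------------------------------------------ alignments

def simulate_alignment(
    tree: Tree5,
    model: SubstitutionModel,
    n_sites: int,
    rate_multiplier: float = 1.0,
    seed: int = 0,
    name: str = "sim",
) -> ProteinAlignment:
    """Evolve sites on the fixed tree; the focal branch is scaled by
    ``rate_multiplier``."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    rates = model.category_rates()
    k = len(rates)
    cats = rng.integers(k, size=n_sites) if k > 1 else np.zeros(n_sites, dtype=int)
    pi = model.frequencies

    bl = tree.branch_lengths.copy()
    bl[4] *= rate_multiplier

    def evolve(parent: np.ndarray, t: float) -> np.ndarray:
        child = np.empty_like(parent)
        for c in range(k):
            p_mat = model.transition_matrix(t, rates[c])
            cum = np.cumsum(p_mat, axis=1)
            sel = cats == c
            u = rng.random(sel.sum())
            rows = cum[parent[sel]]
            child[sel] = (u[:, None] > rows).sum(axis=1)
        return child

    root = (rng.random(n_sites)[:, None] > np.cumsum(pi)[None, :]).sum(axis=1)
    node_a = evolve(root, bl[5])
    node_b = evolve(root, bl[6])
    tips = [
        evolve(node_a, bl[0]),
        evolve(node_a, bl[1]),
        evolve(node_b, bl[2]),
        evolve(node_b, bl[3]),
        evolve(root, bl[4]),
    ]
    rows = ["".join(AA_ORDER[s] for s in tip) for tip in tips]
    return ProteinAlignment(name, list(tree.taxa), rows)


def simulate_protein_set(
    spec: AlignmentSpec,
    model: SubstitutionModel,
    seed: int = 0,
    taxa=("Pminor", "Ptuberculata", "Marsupiomonas", "YPF701", "peDino"),
) -> tuple[list[ProteinAlignment], dict[str, str], GroundTruth]:
    """A full 30+20 protein panel on one tree, per-category multipliers."""
    tree = Tree5(taxa, np.array(spec.branch_lengths, dtype=float))
    truth = GroundTruth(tree=tree)
    alignments = []
    categories = {}
    streams = np.random.SeedSequence(seed).spawn(
        sum(spec.n_proteins.values())
    )
    i = 0
    for category in ("photosynthetic", "non_photosynthetic"):
        mult = spec.rate_multiplier.get(category, 1.0)
        for j in range(spec.n_proteins[category]):
            name = f"{category[:5]}_{j + 1:02d}"
            child_seed = streams[i].generate_state(1)[0] % (2**31)
            aln = simulate_alignment(
                tree, model, spec.n_sites, rate_multiplier=mult,
                seed=int(child_seed), name=name,
            )
            alignments.append(aln)
            categories[name] = category
            truth.categories[name] = category
            i += 1
    return alignments, categories, truth
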