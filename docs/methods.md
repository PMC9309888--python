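# Methods

This note records the models, numerical choices and simulation conditions
behind `plastedit`, and what the tests do and do not demonstrate.

## Coordinates and sequence conventions

All interfaces use 1-based inclusive coordinates (GFF3/GenBank
convention). A feature crossing the origin of a circular molecule is
stored as ≥ 2 segments in *sense* order — on `+` each segment is walked
`start → end`, on `−` `end → start` — never as `start > end`. The GFF3
dialect writes segment lines of one feature (shared `ID`) in sense order,
which makes the reader/writer pair an identity on canonical records.
Lowercase residues are uppercased on read; `U` is rejected in DNA input
(RNA letters appear only in conversion labels); `N` is permitted but
excluded from the GC numerator and denominator, and is never callable as
an edit reference.

The base genetic code is NCBI translation table 11 (bacterial/plastid);
the deviant code is table 11 with AUA reassigned to Met, selected per
genome. The two tables differ at exactly that codon.

## Genome-compaction features

**Intergenic fraction** counts positions covered by no CDS/tRNA/rRNA
feature; overlapping genes do not double-subtract. Pseudogenes count as
genic by default (they are annotated ORFs, drawn as such in genome maps);
a switch excludes them. The coding-site denominator used for editing
percentages is the same union count; because published counts do not
state how doubly covered positions are treated, both the union count and
a sum-with-multiplicity variant (and a CDS-only variant) are computable.

**Inverted repeats** are found by seed-and-extend: exact 20-mer matches
between the sequence and its reverse complement seed "diagonals"
(constant `arm1_position + mirrored arm2_position`), on which arms are
extended. In exact mode every maximal disjoint arm pair of length ≥
`min_arm` (default 1,000 nt — typical plastid IRs are ≫ 1 kb, and only
presence/absence is reported) is returned; this mode is verified against
a brute-force all-substring-pairs oracle. With mismatches allowed
(default ≤ 10 % of the arm), extension uses X-drop scoring (+1 match,
−(1/f − 1) mismatch, so the score is neutral exactly at the allowed
identity; drop-off 5·penalty + 10), trims windows back to matching ends,
and greedily keeps the longest of overlapping hits. The search treats the
genome linearly; an IR spanning the origin of a circular molecule would
be found only after rotating the sequence.

**Pseudogene flags** are advisory. `frameshift_candidate` fires when the
annotated span is not a multiple of 3, or when the annotated frame stops
within the first 90 % of codons while an alternative frame of the same
span runs ≥ 20 codons past that stop; `internal_stop` requires a
well-defined frame (span divisible by 3). The 90 %/20-codon thresholds
are package-defined heuristics, mirrored by an explicit `pseudo`
annotation attribute that curators can set directly. Fusion detection
consumes curated gene assignments (the `gene` attribute list) rather than
running homology search.

**AUA = Met evidence**: for each AUA codon in a query gene, aligned
reference residues vote; a column is Met-conserved (Ile-conserved) when
more than 2/3 of ≥ 3 references agree. A one-sided exact sign test
(q = 0.5) over the informative columns at α = 0.05 yields the verdict
(AUA=Met / AUA=Ile / undetermined). Threshold and α are package choices;
codon-capture reassignment is asserted in the literature without a
stated statistic.

## RNA-editing detection

Published pipelines delegate variant calling to external tools whose
quality score has no closed-form semantics. To make the `qual > 200`
threshold exact and testable, the caller defines an explicit two-model
posterior per pileup column. With per-base error `e_b = 10^(−Q_b/10)`:
M0 (transcript base = genome base) assigns each mismatching read
probability `e_b/3`; M1 (transcript base = the most frequent
non-reference base, ties broken alphabetically) assigns each other read
`e/3` of its own quality. With equal priors,
`qual = −10·log₁₀ P(M0 | data)`. At Q30 with unanimous alternative
reads, 5 reads give qual ≈ 173.8 and 6 reads ≈ 208.6, so 6 is the
minimum clearing coverage — this is asserted analytically in the tests.

A site is reported iff `qual > 200` **and** it lies in ≥ 1 CDS/tRNA/rRNA
feature (pseudogenes included: they are transcribed ORFs). Conversions
are reported on the sense strand of the containing gene (first covering
CDS in annotation order wins over RNA genes; DNA T rendered as RNA U).
Codon categories: ≥ 2 covering CDS → `overlap`; tRNA/rRNA only →
`structural_rna`; otherwise codon position 1/2/3 in the single covering
CDS. No allele-fraction cutoff is applied beyond the posterior;
`edited_fraction` is reported for downstream filtering. Only the dominant
non-reference base is evaluated (multi-allelic columns are not split);
deletion editing is not modeled.

**Insertion edits**: an anchor is reported when one inserted sequence
reaches ≥ 10 supporting reads and ≥ 50 % of reads spanning the anchor
(approximated by column coverage). `frame_restored` is true iff splicing
the insertion into the covering CDS makes the span divisible by 3 and
removes all internal stops under the AUA=Met code; the check assumes a
single-segment CDS, which covers the intended frame-restoration case.

## Branch-length contrast

The tree shape is fixed: the unrooted 5-taxon topology with two enforced
pedinophyte cherries and the peDinoflagellate attached to the central
node — 7 branches total. Likelihoods use Felsenstein pruning over
compressed site patterns, rooted (for computation) at the central
trifurcation; the models are reversible so root placement is immaterial
(checked against a direct sum over internal-node states and under
cherry/role relabelings).

Models: LG (default), WAG, Poisson exchangeabilities; equilibrium or
empirical (+F) frequencies; discrete-gamma rate variation with k = 4
equal-probability categories whose rates are the bin means
(`α` bounds [0.02, 100]). The C60 profile-mixture used in large
phylogenomic analyses is deliberately omitted: for a 7-parameter
branch-length statistic on 5 taxa it is disproportionate, and the
contrast is a rank test, insensitive to monotone changes in the scale of
the estimates.

Optimization is coordinate-wise Brent on each branch (clamped to
[1e−8, 10]), swept in canonical order with α last, until the largest
branch-length change is < 1e−6 or 100 sweeps (non-convergence is flagged,
not raised). Each branch-restricted likelihood is evaluated through the
cached eigendecomposition of the π-symmetrized generator, which reduces
one evaluation to a 20-vector matvec; after convergence, local optimality
is verified by perturbation in the tests.

The per-protein statistic: with `b_f` the focal terminal branch and `S`
the sum of the other six, both the ratio `b_f/S` and the difference
`b_f − S` are computed. The ratio is the default headline (the quantity
is conventionally named and plotted as a ratio) even though a
subtraction-based description also circulates; at fixed `S` the two are
order-isomorphic, so the rank-sum p-value is identical whenever `S` is
constant — tested explicitly. The Wilcoxon rank-sum test reports the rank
sum `W` of the first sample (midranks for ties); exact mode enumerates
all C(m+n, m) assignments (used automatically when m+n ≤ 12 without
ties), otherwise the tie-corrected normal approximation with continuity
correction is used. The 30/20 photosynthetic/non-photosynthetic split of
the 50 plastid proteins ships as `data/protein_categories.tsv`
(30 photosystem/electron-transport/ATPase proteins; 17 ribosomal proteins
plus EF-Tu, Ycf3 and ClpP).

## Synthetic data

One root seed; each component (genome, pileup, alignments) draws from its
own `SeedSequence`-derived stream, so identical seeds give byte-identical
outputs.

*Genomes* (default 20 kb, GC 34.8 %): stop-free ORFs (ATG…stop, 300–900
nt) packed with 50–150 nt spacers; overlapping pairs share 20 nt on
distinct frames of the same strand; fusions carry two gene names;
pseudogenes carry one planted internal stop; the insertion scenario
removes 2 nt from a clean ORF so the genomic frame is broken and the
planted insertion restores it. Codon sampling uses a per-base GC solved
by bisection so that stop-codon rejection still hits the genome-wide GC
target (verified to ±1 % at 50 kb). An optional rotation places the
origin inside the first CDS to exercise origin-wrapping features.

*Pileups*: per-column depth ~ Poisson(coverage, default 50); planted
sites carry the alternative base in an `edited_fraction` of reads
(default 1.0 — complete editing); all other reads err to a uniform other
base with probability ε (default 10⁻³); qualities are constant (Q30).
Planted sites are restricted to positions covered by exactly one CDS so
their category is unambiguous. This emulates the *result* of mapping
RNA-seq reads, not the reads themselves: no mapper biases, read-length
effects, splicing or coverage autocorrelation — passing recovery tests
shows the caller's threshold arithmetic and classification are correct
under the stated noise model, not that any mapper's output is error-free.
Real-data use requires producing the pileup TSV from one's own mapping.

*Alignments*: root states drawn from π, evolved along branches with the
model's transition matrices; the focal terminal branch is scaled by a
per-category rate multiplier. Default panel: 30 + 20 proteins of 2,000
sites on a tree with pedinophyte terminals ≈ 0.05, internals 0.03 and a
0.4 focal branch — branch lengths of the order seen in plastid-protein
trees for these taxa.

## Problem sizes used in the checks

Chosen so the full suite runs in minutes on one CPU: edit recovery
aggregates 100 planted sites × 20 seeded genomes; IR oracle equivalence
uses 50 random 60–140 nt genomes (the O(n³) brute-force oracle bounds the
size); branch recovery uses 50 replicates of 5,000-site LG alignments on
a tree with all branches 0.35 — long enough that ±10 % recovery of every
branch is statistically achievable at that alignment length (relative
error of internal-branch estimates is the bottleneck); the contrast power
experiment uses the default 30+20 × 2,000-site panel, 100 replicates,
with a 2× focal multiplier on the non-photosynthetic category (power at
α = 0.01) and with no effect (calibration at α = 0.05). Single-rate
(no-Γ) fitting is used in the recovery/power experiments since the data
are simulated without rate variation.

## Known limitations

- The caller models substitutions and insertions only; deletion editing
  and partial-editing mixtures beyond a single dominant allele are out of
  scope.
- The IR search is linear in the genome; origin-spanning IR arms require
  rotating the sequence first.
- `detect_insertion_edits` approximates "reads spanning the anchor" by
  column depth and assumes single-segment CDS for the frame check.
- The contrast machinery fixes the 5-taxon shape; it is not a general
  tree-search or model-selection tool.
- Bundled published per-type edit counts are inputs for arithmetic
  cross-checks; reproducing the original counts end-to-end would require
  the deposited reads and genomes plus a read mapper, which the package
  deliberately does not include.
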