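# plastedit

Comparative plastid genomics for green-plastid dinoflagellates
("peDinoflagellates" — dinoflagellates whose plastid derives from a
pedinophycean green-algal endosymbiont, such as *Lepidodinium
chlorophorum* and strains MGD/TGD). The package implements the three
computational stages of such a study as a tested, reusable pipeline:

1. **Genome-compaction features** — GC content, intergenic fraction,
   inverted-repeat (IR) detection by seeded extension, ORF overlap and
   fusion detection, pseudogene flagging (internal stops, frameshift
   candidates), and sign-test evidence for the deviant **AUA = Met**
   genetic code.
2. **RNA-editing detection** — calls RNA–DNA differences from per-position
   pileups under an explicit two-model Phred posterior
   (`qual = −10·log₁₀ P(transcript = genome | reads)`), keeps sites with
   `qual > 200` that lie in coding regions, classifies them strand-aware
   into the 12 base-conversion types (A→G, U→C, …) and codon-position
   categories, and detects base-insertion editing that restores a broken
   reading frame (the *psaA*-like case).
3. **Branch-length contrast** — optimizes the 7 branch lengths of the fixed
   unrooted 5-taxon tree `((Pm,Pt),(Mars,YPF),peDino)` per protein
   alignment by Felsenstein pruning under LG/WAG/Poisson (+F, discrete-Γ)
   models, computes the per-protein focal-branch statistic
   (ratio `b_f/S` and difference `b_f − S`, with `S` the summed length of
   the other six branches), and contrasts photosynthetic vs
   non-photosynthetic proteins with a Wilcoxon rank-sum test.

A seeded synthetic-data generator (`plastedit.simulate`) produces circular
genomes with overlapping/fused/pseudogenized ORFs, pileups with planted
edits at chosen coverage/quality, and alignments evolved on the 5-taxon
tree — with full ground truth — so every stage is exercisable without
downloads.

## Worked example

Simulate a 20 kb genome with 23 planted conversion edits and one planted
2-nt insertion edit, then run all three stages:

```bash
plastedit simulate --config simcfg.yaml --out-dir sim
plastedit features --genome sim/genome.fasta --gff sim/annotation.gff3 \
    --min-arm 1000 --out sim/features.tsv
plastedit edits --genome sim/genome.fasta --gff sim/annotation.gff3 \
    --pileup sim/pileup.tsv --out-prefix sim/edits
plastedit contrast --aln-dir sim/alignments --categories sim/categories.tsv \
    --focal peDino --model LG --out sim/contrast.tsv
```

The `edits` command prints

```
23 edit sites (0.2032% of coding sites), 1 insertion edits
```

— all 23 planted conversions were recovered (none missed, no false
positives at coverage 50×/Q30), amounting to 0.20 % of the coding
positions, and the planted frame-restoring insertion was found. The first
rows of `sim/edits.sites.tsv`:

```
position  features  conversion  qual     edited_fraction  codon_category
152       orf014    A>G         1807.88  1.0              3
1079      orf001    C>U         1634.04  1.0              3
1661      orf002    U>C         1807.88  1.0              2
```

`qual` is the Phred-scaled posterior against the unedited model — 50
unanimous alternative reads at Q30 give quality far above the 200
threshold (6 such reads are the minimum that clears it).
The `contrast` command prints the rank-sum verdict, e.g.

```
W = 6.0, two-sided p = 0.1 (non_photosynthetic > photosynthetic)
```

(in this toy run 3 vs 3 proteins with a 2× focal-branch rate multiplier:
p = 0.1 is the smallest value the exact test can produce at these sizes,
with all three non-photosynthetic ratios above all three photosynthetic
ones).

The library API mirrors the CLI: `summarize_genome`,
`call_base_conversions`, `detect_insertion_edits`,
`optimize_branch_lengths`, `run_category_contrast`, etc. — see the module
docstrings and `docs/methods.md` for the model details.

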