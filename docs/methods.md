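# Methods

This note documents the models, defaults and numerical choices behind
`foramtx`, and what the synthetic tests do and do not establish about real
sediment metatranscriptomes.

## The activity statistic and why it is presence/absence

Low-input RNA-seq libraries built with single-primer isothermal amplification
(SPIA) show orders-of-magnitude variation in per-transcript read depth
between technical replicates, while the *set* of detected transcripts stays
nearly constant. Depth-based normalizations (RPKM and relatives) inherit that
variance; counting each expressed ORF once does not. The pipeline's central
quantity is therefore the per-sample fraction of unique assigned ORFs per
taxon group, over all assigned ORFs (the eukaryote-vs-prokaryote view) or
over eukaryote-assigned ORFs only (the protist-group composition view).
An RPKM implementation ships in `profiles.rpkm` purely so tests can
demonstrate the contrast; it is not a supported output.

Two consequences are tested as invariants: group fractions sum to 1 whenever
any ORF is assigned, and multiplying any transcript's read count by any
positive factor leaves every profile unchanged. "Unique ORF" is keyed by ORF
id within one sample's assembly; cross-sample ORF clustering is out of scope.
Fold changes between conditions aggregate replicates by the mean of
fractions (the per-replicate ratio range is reported alongside); averaging of
fractions rather than pooling of counts is also used for KOG pie-chart-style
summaries, with pooling available to callers that want it.

## ORF calling

A deliberate simplification stands in for the two production gene callers:
a six-frame scan reporting, per stop-bounded segment, the ORF from its first
start codon (ATG in eukaryote mode; ATG/GTG/TTG in prokaryote mode) to the
stop, inclusive. ORFs reaching a contig edge without a stop are reported and
flagged partial, because transcript fragments are common in
metatranscriptome assemblies. Coding-potential scoring (Markov-model or HMM
stages of the production tools) is not reimplemented — the downstream
statistic needs coordinates and translations only — and externally produced
ORF tables in the same TSV schema are accepted. Defaults: minimum contig
300 nt (the assembler's minimum, kept as input validation), minimum ORF
100 aa (a conventional default; configurable). Coordinates are 0-based
half-open internally and 1-based inclusive in written tables. ORF ids encode
contig and coordinates, so the two calling modes agree on identity and can
be merged safely.

## Annotation

Hits are filtered at minimum bit score 50, minimum percent identity 30 and
minimum alignment length 50 residues; all bounds are inclusive ("minimum 50"
is read as ≥ 50). "Amino acid similarity" is implemented as percent identity
(the tabular `pident` convention). The best hit per ORF is the maximal bit
score, ties broken by lower e-value then lexicographic subject id, making
assignment order-independent. Taxonomic resolution stops at (group, genus) —
homology against a sparse reference set cannot separate congeneric species.

External 12-column tabular hits are accepted directly. The built-in aligner
(Smith–Waterman, affine gaps, BLOSUM62 11/1) exists so the pipeline runs at
desk scale with no external binaries; bit scores use the gapped
Karlin–Altschul convention (λ = 0.267 nats, K = 0.041), configurable. The
search applies a shared 6-mer prefilter before alignment (a seed heuristic in
the style of fast protein aligners); exhaustive search is available and the
two are verified equivalent in tests. Contaminant filtering removes ORFs
whose assigned genus is on a blocklist (default: seven skin/soil genera
recurrent in reagent kits and laboratory dust); the contaminant fraction is
computed over assigned ORFs and a warning fires at ≥ 10%.

## Synthetic community generator

The generator is the package's instrument for making the analysis testable,
and its defaults are the study conditions the tests assume:

- **Taxa**: one Foraminifera-like target group, several other protist groups,
  Bacteria/Archaea, and optional contaminant taxa whose genus sits on the
  blocklist. Genes are back-translated from random proteins with synonymous
  codons weighted toward each taxon's GC; each gene is framed ATG…stop with
  an in-frame stop placed immediately 5′ of the start inside the UTR, so the
  planted ORF is exactly recoverable by the caller.
- **Expression**: per sample, each taxon transcribes a programmed fraction of
  its genes; the transcribed set is keyed by (spec seed, sample id) so
  technical replicates share composition exactly. A gene appears as a contig
  iff transcribed — assembly is out of scope, so contigs are pristine
  (no chimeras or fragmentation).
- **Amplification bias**: each transcript's read-pair count is
  depth_weight × A with A ~ log-normal(0, σ²), i.i.d. per transcript and
  replicate; σ defaults to 2.0, putting the per-transcript depth CV near
  e² ≈ 7 — the heavy-tailed, orders-of-magnitude regime that motivates
  presence/absence normalization. Sequencing error is substitution-only;
  qualities are constant Phred 30 (quality-aware processing is not part of
  the computation under study). Read geometry defaults to 2 × 150 nt with
  350 ± 50 nt inserts; these are configurable conventions, not asserted
  properties of any particular instrument run.
- **18S read sets**: whole molecules are sheared into consecutive fragments
  with random phase, so molecule termini are fragment boundaries and the
  reference ends get covered the way real cDNA fragmentation covers them;
  molecules are added until emitted bases reach coverage × length, pinning
  realized mean coverage to the request.

What passing tests show: the pipeline recovers programmed compositions,
enrichments and barcodes from data with exactly this structure. What they do
not show: robustness to mis-assembly, chimeras, indel error, strand bias,
incomplete reference databases or genuinely novel taxa — real-data effects
the generator intentionally omits.

## Greedy 18S extension

Seeds are OTUs with a nucleotide-similarity hit to a full-length 18S
reference at e-value ≤ 1e-10, optionally restricted to hits overlapping the
3′ 1000-nt barcoding window. Ten bases are trimmed from both seed ends
(erroneous terminal bases). Per iteration: reads overlapping the consensus by
≥ 30 nt at ≥ 95% identity are recruited in either orientation (the 95%
mirrors the read-mapping identity used for contig mapping); mates of
edge-recruited reads may anchor at a relaxed 80% identity (pair rescue);
each end grows by the column-wise majority of recruited overhangs, with
majority ties emitting IUPAC codes rather than arbitrary picks; interior
columns with coverage ≥ 3 are corrected to the column majority — the
automated analogue of manual error correction against mapped reads. A read
may extend an end only when its overlap anchors flush at that end, a guard
against repeat-induced chimeras. The loop stops when neither end grows or at
20 iterations; reads are re-mapped from scratch each iteration. Read mapping
is ungapped (substitution-only), matching the generator's error model;
indel-rich data should be mapped externally and supplied as trimmed reads.
Barcode extraction locates the consensus on the reference by semi-global
alignment and cuts the intersection with the 3′ window, flagging partial
coverage and counting differences.

## Community statistics

Bray–Curtis dissimilarity on fractional vectors (group fractions, or KOG
fractions within the target group) is the default feature space and metric;
Jaccard on ORF presence sets is available. The distance between two all-zero
vectors is defined as 0 and flagged. ANOSIM uses Clarke's R on midranked
distances with a seeded permutation p-value,
p = (1 + #{R_perm ≥ R_obs}) / (1 + B); when the number of distinct label
arrangements is ≤ B the exact distribution is enumerated instead (for the
9-sample 2/4/3 incubation design that is 1260 arrangements, an exact floor
of p = 1/1260 ≈ 0.0008). One reporting caveat is intentional: ANOSIM yields
R, not R²; this implementation reports R and never squares it. Singleton
groups are permitted with a warning. UPGMA merges the pair of clusters at
minimal average distance, at node height = half that distance (so cophenetic
distances reproduce average-linkage distances exactly); ties break on the
lexicographically smallest member-name pair, making the tree deterministic.

## Problem sizes and calibration

The test and acceptance workloads were sized for a single CPU: oracle
equivalence on 200 random contigs and 30 alignment pairs; a 470-protein
reference database with ~200–400 ORFs per sample for the end-to-end 25×
enrichment recovery; 20 seeded references at 50× (error-free) plus one at
125× with 1% error for extension recovery; and 500 null simulations at 199
permutations each for ANOSIM type-I calibration. The ANOSIM power check uses
4 + 5 samples with target fractions programmed at 0.05 vs 0.5, where the
exhaustive 126-arrangement distribution gives a minimal p of ≈ 0.0079.

## Known limitations

Single (standard) genetic code; no intron or splice handling; no LCA-style
multi-hit taxonomy; the extension consensus is haploid (no mixed-template
deconvolution beyond IUPAC ambiguity); PERMANOVA/NMDS and phylogenetic
distances are out of scope, as is tree inference beyond UPGMA.
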