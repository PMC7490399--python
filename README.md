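# foramtx

Presence/absence activity profiling of benthic Foraminifera from sediment
metatranscriptomes.

Benthic Foraminifera are shelled marine protists that persist — and can even
thrive — in anoxic, sulfidic sediments. Quantifying their activity from bulk
sediment RNA-seq is awkward: the single-primer isothermal amplification (SPIA)
used by low-input RNA-seq kits biases per-transcript read depth by orders of
magnitude between technical replicates, so depth-based measures such as RPKM
are unreliable. What *is* stable across replicates is the **set** of unique
expressed ORFs. `foramtx` implements the analysis built on that observation,
for microbial ecologists working with mixed-community (meta)transcriptomes:

- six-frame ORF calling on assembled contigs (eukaryote-style ATG starts, or
  prokaryote-style with GTG/TTG alternative starts);
- thresholded best-hit homology annotation against a taxon/KOG-labelled
  protein database (minimum bit score 50, percent identity 30, alignment
  length 50 residues), with contaminant-genus filtering and a warning when
  contamination reaches 10% of assigned ORFs;
- the activity statistic itself: per sample, the fraction of unique assigned
  ORFs per taxon group, plus within-group KOG-class composition and
  between-condition fold changes;
- greedy iterative seed extension that reconstructs the ~1000-nt 3′ 18S rRNA
  barcode of the active taxa from the reads, with per-base coverage;
- community statistics: Bray–Curtis / Jaccard distances, the ANOSIM
  permutation test (Clarke's R, exact enumeration when feasible), and UPGMA
  clustering;
- a synthetic-community generator that reproduces the statistical structure
  of such data (programmed expression shifts, log-normal amplification bias,
  planted contaminants, sequencing error), so the whole pipeline is testable
  without external data.

## The statistic

For sample *s* and taxon group *g* (e.g. Foraminifera), let *U<sub>g,s</sub>*
be the number of distinct ORFs whose best database hit passes the thresholds
and belongs to group *g*. The activity readout is the fractional abundance

> f<sub>g,s</sub> = U<sub>g,s</sub> / Σ<sub>g′</sub> U<sub>g′,s</sub>

computed on presence/absence only — an ORF seen with 1 read and one seen with
10,000 reads contribute equally, which makes f invariant to per-transcript
amplification bias by construction. Fold changes between conditions are
ratios of replicate-averaged fractions. Group differences are tested with
ANOSIM on ranked pairwise dissimilarities:

> R = (r̄<sub>between</sub> − r̄<sub>within</sub>) / (n(n−1)/4),  R ∈ [−1, 1]

with a permutation p-value (exact enumeration of label arrangements whenever
their number does not exceed the requested permutations).

## Worked example

The one-command synthetic demonstration generates a six-sample, two-condition
community (three oxic and three anoxic replicates, with the target group
programmed to express more of its genes under anoxia plus a planted
*Pseudomonas* contaminant), then runs every stage:

```bash
foramtx run-all --synthetic --outdir demo --seed 3
# completed 7 stages -> demo
```

`demo/manifest.json` records, per stage: 6 samples against a 148-protein
reference database; 682 called ORFs; 492 hits kept at the 50/30/50
thresholds; ~2–3% contaminant ORFs removed per sample (below the 10% warning
level); and the headline results

```
fold_change: Foraminifera oxic -> anoxic, ratio 5.617
anosim: R = 1.0 (exhaustive, 20 label arrangements)
```

i.e. the Foraminifera fraction of unique expressed ORFs rises from 0.061
(oxic) to 0.340 (anoxic), a 5.6-fold increase matching the programmed
enrichment, and the two condition groups separate perfectly (R = 1; with
3+3 samples the exact p cannot go below 2/20 = 0.1 — small designs bound the
attainable significance). The extension branch rebuilds the full-length 18S
reference from simulated reads (consensus 1565 nt, mean coverage 40×) and
`demo/upgma.nwk` holds the sample dendrogram:

```
(((anoxic_r1:0,anoxic_r2:0):0,anoxic_r3:0):0.14,((oxic_r1:0,oxic_r2:0):0,oxic_r3:0):0.14);
```

Every stage is also callable on its own (`foramtx orfs / annotate / profile /
extend / stats`) on externally produced FASTA/TSV inputs — see `--help` on
each subcommand — and the library API mirrors the CLI one-to-one.

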