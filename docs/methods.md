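# Methods

This note documents the models and procedures implemented in `srnakit`,
the parameter defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Pipeline model

The package implements the classic small RNA-seq profiling recipe for a
paired tumour/normal design:

1. **Adapter clipping.** For each read, every occurrence of the 3′
   adapter — full-length or as a prefix overhanging the read end — is
   scored by Hamming distance. A candidate is valid when its mismatch
   count is at most 0.1 of the aligned length and the overlap is at
   least 3 nt; among valid candidates the one with the most matching
   bases wins (ties: fewer mismatches, then leftmost). These are the
   cutadapt defaults; the protocol names the tool but not the knobs.
   `N` never matches anything, including another `N` — the conservative
   aligner convention.
2. **Quality trimming** (Phred cutoff 20, SANGER offset 33) uses the
   BWA partial-sum rule: at the 3′ end, then the 5′ end, the segment
   maximising Σ(cutoff − q) is removed if that sum is positive. The
   order — adapter first, then quality — follows the protocol's stated
   order and can be inverted with `RunConfig.trim_quality_first`.
3. **Length filter**: reads shorter than 15 nt (inclusive threshold)
   are discarded. Reads clipped to length 0 count as discarded, not as
   kept-empty.
4. **UniTag collapse**: identical sequences across all libraries become
   one tag with per-library counts; tags seen exactly once in the whole
   dataset (singletons) are removed. Whether singleton removal should be
   per-library or dataset-wide is not specified anywhere we know of;
   dataset-wide is the stricter choice and is what the collapse invariant
   (`Σ totals + singletons = input reads`) assumes.
5. **Mapping** re-implements the bowtie `-v 2 --best --strata -k 50`
   policy by exhaustive scan: Hamming distance (no indels, `-v`
   semantics, mismatches counted over the whole tag), both strands, at
   most 2 mismatches; only the best (minimum-mismatch) stratum is
   reported; a tag with more than 50 candidate loci is suppressed
   entirely. The >50 cap is evaluated on the *pre-stratum* candidate set
   (bowtie `-k` suppresses the read, not the surplus alignments); the
   wording of the original description covers either reading, so
   `AlignPolicy.cap_post_stratum` switches to the other. This is a
   policy re-implementation for desk-scale genomes (≲ 1 Mb); for real
   genomes, externally produced SAM can be imported (`align.import_sam`)
   and is re-filtered under the identical policy.
6. **Annotation and fractional counting.** A tag is excluded when any
   of its retained loci overlaps a coding exon on either strand — the
   strictest reading of coding-exon exclusion, applied at tag level.
   Otherwise each locus is assigned to the same-strand sncRNA feature
   covering ≥ 50 % of the tag, with class priority miRNA > snoRNA >
   tRNA fragment > other ncRNA (threshold and priority are package
   choices, exposed in `RunConfig`). A tag of count *c* with *L* loci
   contributes *c/L* per locus; intergenic loci absorb their share, so
   mass is conserved exactly (tested at 1e-9 per library).
7. **NEV normalisation.** The normalised expression value is
   reads-per-million by default: NEV*ij* = 10⁶·*k<sub>ij</sub>*/*T_j*,
   with *T_j* the library's total mapped mass when available (the
   pipeline passes it), else the column sum of assigned counts. A
   `size_factor` mode (counts divided by median-of-ratios factors) is
   available. The exact NEV scale of the original tool is not
   recoverable; only ratios of NEVs are ever compared, and the DE test
   always works on raw fractional counts with size factors regardless of
   the display normalisation.

## Differential expression model

Counts follow the DESeq-family negative binomial, Var = μ + αμ².

* **Size factors**: *s_j* = median over features with nonzero geometric
  mean of *k<sub>ij</sub>* / (Π*_j k_ij*)^(1/m).
* **Dispersions**: per-feature method of moments on the pooled
  within-group variance *w_i* of normalised counts,
  α̂*_i* = (*w_i* − ξ·μ*_i*)/μ*_i*², with ξ = mean(1/*s_j*) the
  shot-noise scale; a trend a₀ + a₁/μ is fitted by least squares over
  features with α̂ > 0; the final dispersion is max(α̂, trend(μ)) — the
  conservative sharing rule of the cited method family. On Poisson data
  (9 vs 9) the median final α is ≤ 0.05; at true α = 0.2 the median
  lands in [0.1, 0.4] (both verified by simulation in the test suite).
* **Exact test**: group totals K_A, K_B (fractional sums rounded
  half-to-even — the NB pmf needs integers; NEVs stay fractional). Under
  the null the pooled per-unit mean is μ = K_S/Σs; each group total gets
  mean μ·S_g and variance μ·S_g + αμ²·Σ<sub>j∈g</sub>s_j². The p-value
  sums P(a)·P(b) over all splits a+b = K_S with probability at most the
  observed split's, normalised by the total over all splits (without the
  normalisation the Poisson-limit equivalence with the conditional
  binomial test would not hold; it is verified to 1e-6 in the tests).
  The implementation agrees exactly with full enumeration using
  independent lgamma-based pmfs on hundreds of random instances.
* **Multiple testing**: Benjamini–Hochberg step-up, significance at
  FDR < 0.1 (enrichment uses FDR < 0.05).

**Outlier screening** precedes testing: PCA on log₂(NEV+1) (features
centred; the log transform stabilises variance and is switchable), and a
sample whose PC1 or PC2 score deviates from the mean score by ≥ 4
population SDs (n denominator) is flagged; both members of a flagged
patient pair are removed. Detection is single-pass — no re-iteration
after removal. Note an algebraic bound worth knowing: a single extreme
sample among m can reach at most √(m−1) population SDs, so the 4-SD rule
needs m ≥ 18 samples to be able to fire at all.

## Network construction

Interaction evidence rows (miRNA, gene, database) are case-normalised
and deduplicated; support counts *distinct* database names, never rows.
An edge requires support ≥ 3 (of 7) and inverse expression between a
significantly deregulated miRNA and a listed DE gene. Gene matching is
case-insensitive exact; alias resolution is an input concern. GO
enrichment is the hypergeometric upper tail P(X ≥ k | N, K, n) with BH
correction; the universe defaults to all genes in the GO map. Enriched
categories expand to sub-networks merging supplied PPI edges among
category genes with the targeting edges into them.

## Synthetic data: what it emulates, and what it does not

The generator (`srnakit.synthetic`) produces a ~100 kb random genome
with 95 non-overlapping features — 60 miRNA records (lengths 20–23 nt
with 22 most likely, two miRNAs planted at three identical loci each to
exercise fractional counting), 10 snoRNAs, 5 tRNA-fragment sources, 20
coding exons, both strands used. Libraries follow a paired design
(default 9 pairs, 20 000 reads per library): per-feature counts are NB
draws with library size factors log-uniform on [0.5, 2] and dispersion
α = 0.1; reads are the mature sequence (±1 nt end offset with
probability 0.1), the 3′ adapter, and random filler to a fixed 36 nt
machine length (not stated by the emulated protocol; fixed so clipping
is always exercised). Insert qualities are ≥ 34 with a sub-20 decaying
tail; 5 % of reads are degradation fragments (random genome slices,
8–30 nt, whose short end exercises the length filter) and ≥ 10 unique
singleton sequences per library are planted. Spiked features (default
20, |log₂FC| = 2, means in [100, 500]) are confined to miRNAs/snoRNAs.
The optional planted outlier library receives a per-feature 2^N(0, 5)
multiplicative distortion (clipped at ±9, rescaled to preserve depth) —
large enough, given the √(m−1) bound above, that the displaced library
exceeds the 4-SD criterion by construction. Evidence tables plant true
target pairs (3–7 supporting databases), low-support decoys (1–2),
same-direction decoys (up to 7), and one GO category enriched by
construction (15 of 20 members in the up list against a ~500-gene
universe).

What passing tests on this data do **not** show: real miRNA sequence
content and isomiR biology beyond ±1 nt offsets; genome-scale mapping
ambiguity (repeats, paralogous families); adapter chemistry artefacts;
library-preparation biases that violate the NB model; and database
alias/versioning noise in interaction evidence. Results on synthetic
data demonstrate correctness of the algorithms under their stated
assumptions, not performance on any particular real dataset.

## Problem sizes and determinism

The validation suite runs the read-level study at 10 pairs × 20 000
reads (≈ 480 k reads) and the null error-control study at 500 features ×
18 libraries — sizes chosen so the complete suite and the acceptance
script each run in about a minute on one core while leaving the
statistical checks well-powered. All randomness flows from a single root
seed through named substreams (`SeedSequence(seed, spawn_key=crc32(name))`),
so every artefact — FASTQ bytes included — is reproducible bit-for-bit;
re-running the pipeline with the same configuration and seed yields
identical checksums in the run manifest. Degenerate inputs are handled
explicitly: empty FASTQ streams, all-zero libraries (error naming the
library), zero-variance PCA (warning, no outliers), K_S = 0 (p = 1),
fewer than two significant features (clustering skipped with a warning),
and fewer databases than the support threshold (warning).

## Known limitations

* The exhaustive aligner is O(genome × tags) and intended for synthetic
  or targeted genomes; real-genome runs should import SAM.
* The exact test enumerates K_S + 1 splits; for very deep libraries
  (K_S ≫ 10⁶) a normal approximation would be needed (not implemented).
* Only two-group paired designs are supported; no GLM framework, no
  shrinkage estimators beyond the max-sharing rule.
* The NEV reported is a display normalisation; cross-study comparison
  of absolute NEVs is not meaningful.
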