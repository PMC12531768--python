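# Methods

This note documents the models and procedures implemented in `enhmut`,
the defaults and the reasoning behind choices that were genuinely open.

## Coordinate conventions

Interval data (BED, enhancer peaks, conserved elements, coding exons)
are 0-based half-open. Mutation positions and TSS coordinates are
1-based (VCF convention); a point mutation at `pos` occupies interval
`[pos−1, pos)`. Chromosome names are matched as exact strings.
Multi-allelic rows are rejected — the filter thresholds are per-allele,
so callers must pre-split.

## Somatic filter

A candidate variant of one patient, observed across all of that
patient's tumor samples plus the matched normal, passes iff

| clause | default |
|---|---|
| normal depth ≥ `min_normal_depth` | 10 |
| normal alt reads ≤ `max_normal_alt` | 2 |
| normal VAF < `max_normal_vaf` | 0.02 |
| tumor depth ≥ `min_tumor_depth_all_samples` in **all** samples | 20 |
| ∃ sample with tumor alt ≥ `min_tumor_alt` **and** tumor VAF ≥ `min_tumor_vaf` | 10, 0.05 |

VAF is alt/depth with 0/0 defined as 0. Open design points, resolved as
follows: the tumor-support read-count and VAF clauses must hold
*jointly in the same sample* (the stricter and more common reading of
the two conditions listed together); the rejection reason names the
first failed clause in the order above. A passing variant is scored
present in a sample when that sample has ≥ `min_presence_reads`
supporting reads (default 1). This read-count presence rule replaces
probabilistic presence models used by phylogeny tools; given a presence
matrix the clonality rule itself (clonal ⇔ present in all samples) is
deterministic.

The filter is monotone (relaxing any threshold can only grow the
passing set) and partitions its input; both properties are tested.

## Region atlas

Four mutually exclusive labels with precedence
coding > promoter > enhancer > noncoding-NOS; lower-precedence sets are
clipped, and noncoding-NOS is the complement, so label footprints sum
exactly to the genome size.

* **Promoter** = TSS ± 2,000 bp, inclusive on both sides (4,001 bp
  before clipping). No external promoter catalog is consumed; the ±2 kb
  half-width mirrors the enhancer exclusion radius so that the promoter
  and enhancer definitions tile the TSS neighborhood complementarily.
  Configurable.
* **Enhancer** = scored peaks with score **strictly** greater than 50
  ("more than 50" read literally), merged, then restricted to peaks
  whose distance to the nearest TSS lies in [2,000, 50,000] bp
  inclusive. Distance is measured from the nearer peak **edge** to the
  TSS and is 0 when the TSS falls inside the peak (peaks containing a
  TSS are therefore excluded as promoter-proximal). Edge distance is
  the conservative literal reading; midpoint distance is not used.
* Burden denominators are the atlas footprints, identical for all
  samples; no per-sample callable-region correction is applied.

The same TSS-to-edge distance convention is reused for nearest-gene
assignment, so one definition serves the whole package.

## Signatures

Spectra use the standard 96 pyrimidine-centered channels, ordered
substitution-class major (C>A, C>G, C>T, T>A, T>C, T>G) with the 16
flank contexts alphabetical by (5′, 3′) base; purine-reference
substitutions are reverse-complemented. Indels and chromosome-edge
positions are skipped with logged counts; a ref-allele mismatch against
the reference sequence is an error, not a skip.

Exposures are obtained by **refitting**, not de novo extraction: the
normalized spectrum is decomposed over a fixed catalog by non-negative
least squares and the weights renormalized to sum to 1; the NNLS
residual norm is reported as reconstruction error. Refitting matches
how per-sample proportions of named signatures are reported in
practice, and is recoverable by construction from the generator's
mixtures (±0.05 per weight at 2,000 mutations in the test conditions).

The shipped catalog (`signatures.synthetic_catalog`) is **synthetic**:
its columns carry the names SBS1, SBS5, SBS8, SBS18, SBS39, SBS40 and
SBS41, but the probability vectors are deterministic constructions that
echo each namesake's dominant substitution class (SBS1: C>T at CpG;
SBS18: C>A; SBS39: C>G; SBS41: T>A; SBS5/SBS40: flat profiles). They
are mutually well separated, which is what refitting and recovery
experiments require; they are not reference data and carry no etiology.
Any 96-row catalog TSV can be substituted via `read_signature_catalog`.

Comparative statistics:

* **Friedman test** across the four region classes blocked by sample
  (scipy implementation, average ranks, tie correction). A table in
  which every sample has identical weights across regions returns
  P = 1 by convention. Verified against the direct rank formula to
  1e−9.
* **Wilcoxon signed-rank** for paired group comparisons: zero
  differences dropped, exact null for ≤ 25 informative pairs, normal
  approximation with continuity correction above; all-zero differences
  return P = 1. Verified against exhaustive sign-flip enumeration.
* **Two-stage adaptive FDR** (Benjamini–Krieger–Yekutieli): stage 1
  runs BH at q′ = q/(1+q), estimates m̂₀ = m − r₁ true nulls, stage 2
  reruns BH at q′·m/m̂₀ (statsmodels `fdr_tsbky`, one iteration). This
  is the published definition-6 procedure with the q/(1+q) correction
  at both stages — the variant with the proven FDR ≤ q guarantee.
  Measured empirical FDR under 1,000 uniform nulls + 50 Beta(1,50)
  signals is ≈ 3.8%.
* **PCA** of exposure matrices: centered, unscaled SVD with component
  signs fixed by making each loading vector's largest-magnitude entry
  positive (computed directly so the sign convention is explicit).
  Hierarchical clustering of exposures (average linkage, Euclidean) is
  provided as a reporting aid only.

## Conserved-enhancer recurrence

An enhancer is conserved iff it shares ≥ 1 bp with any conserved
element (half-open semantics: abutting intervals do not overlap). Each
conserved enhancer is assigned its first and second nearest genes
within 500 kb, anchored at the TSS (gene bodies are not used as
anchors); ties at identical distance are broken lexicographically by
gene id, both tied genes remaining eligible. Recurrence is counted at
the **gene** level: a gene accrues a sample (and its patient) whenever
any of its assigned conserved enhancers carries a passing mutation in
that sample; both assigned genes of an enhancer share credit, sets are
deduplicated, and mutations in unassignable enhancers are tallied under
an `unassigned` sentinel that is never reported as recurrent.

## Expression association

The group comparison is the **two-sample Wilcoxon rank-sum
(Mann–Whitney) test**, not the signed-rank test: enhancer-mutant and
wild-type samples are independent groups, not pairs. Samples with a
coding mutation in the tested gene are excluded first (a coding hit can
change transcript abundance by itself), and only samples present in the
expression matrix (optionally restricted to a WGS–RNA matched set)
enter. Genes with no mutant or no wild-type eligible sample are skipped
with a logged reason rather than reported at P = 1 — the test is
undefined there.

The adjusted P permutes the mutant-label assignment uniformly over the
*eligible* samples (preserving the per-gene mutant count; the
permutation universe equals the test universe), recomputes the rank-sum
P for each of B = 10,000 draws, and reports the proportion of reference
P values **strictly below** the observed one. This is the literal
proportion estimator, which can return 0; a `(k+1)/(B+1)` estimator is
available behind a flag for users who prefer a never-zero, positively
biased estimate. P-value computation is identical for the observed and
permuted statistics: exact null when the pooled sample is tie-free with
≤ 30 values, tie-corrected normal approximation with continuity
correction otherwise (matching scipy's asymptotic Mann–Whitney P). The
permuted statistics are computed vectorized from pooled ranks and
mapped to P values through that same routine, and an exhaustive
enumerator over all C(n, k) assignments is exposed for small instances;
the Monte-Carlo estimate converges to it (within 0.02 at B = 10,000 on
a C(6,2) instance, by test).

## Synthetic cohort generator

The generator emulates a multi-region whole-genome cohort of an
advanced solid tumor:

| parameter | default | rationale |
|---|---|---|
| patients × samples | 10 × 8 | cohort of 10 patients, ~10 regions each; 8 keeps desk-scale runtime |
| untreated region rates (mut/Mb) | coding 1.30, promoter 1.86, enhancer 1.52, noncoding-NOS 2.48 | reported untreated medians per region class |
| treatment multiplier | 3.8 on 60% of patients | treated tumors carry ~3.8-fold more mut/Mb; 6/10 patients treated |
| clonal fraction | 0.8 | the majority of mutations predate the most recent common ancestor |
| conserved enhancer fraction | 0.145 | 8,966 / 62,015 conserved enhancer regions |
| decoy fraction | 0.2 of variant rows | the filter must demonstrably remove known-bad rows |
| tumor / normal coverage | 80× / 40× (negative binomial, dispersion 10) | typical tumor/normal WGS depths |
| planted expression shift | −3.32 log2 | ~10-fold downregulation in mutant samples |
| planted events | 2 genes, 4 mutant samples from 3 patients each | recurrence above the 3-sample / 2-patient thresholds |

Mechanics worth knowing:

* **Context placement** (default): each mutation's channel is drawn
  from the region's signature mixture, then a genomic position matching
  that trinucleotide context is drawn uniformly within the region's
  footprint. Spectra therefore reproduce the mixture exactly up to
  multinomial noise, making refitting recoverable. Requires sequence.
* **Uniform placement**: positions drawn uniformly within footprints,
  no sequence or context bookkeeping. This scales to multi-gigabase
  footprints and is what the burden-recovery experiments use (the
  planted rates of a few mut/Mb only yield ≥ 5,000 mutations per sample
  on ~1.9 Gb of footprint).
* Per-sample, per-region mutation counts are exactly Poisson with mean
  rate × footprint: clonal counts are Poisson(c·λ) shared by all
  samples, and subclonal variants are drawn Poisson(2(1−c)·λ) and
  assigned to uniform nonempty proper sample subsets, whose expected
  per-sample membership is exactly 1/2 for any number of samples.
* True somatic variants are constructed to pass the filter (depths
  clamped above the coverage clauses; one anchor sample forced above
  the tumor-support clause; present samples forced to ≥ 1 read), and
  each decoy violates exactly one clause (germline-like normal support,
  low normal coverage, one low-coverage tumor sample, or < 10 alt reads
  everywhere). Filter recall/precision against truth is therefore
  exactly 1 by design, and deviations indicate implementation bugs —
  which is the point.
* Expression is gene-baseline (5.0 log2 units) + Gaussian noise
  (σ = 0.5), with planted shifts added to the event gene in its mutant
  samples. Every coding mutation counts as expression-excluding;
  synonymy is not modeled.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: copy-number alteration and
ploidy, purity variation, sequencing error and mapping artifacts
(decoys are threshold-violations, not error processes), realistic gene
density/length distributions, linkage between enhancers and their
target genes beyond proximity, correlated expression programs, and
cohort-level biological heterogeneity. Results on real cohorts depend
on upstream calling quality in ways the synthetic truth cannot probe.

## Problem sizes used in tests and the acceptance script

Unit and integration tests run on 2 Mb toy genomes (10 × 8 cohort,
~180 variants). The larger experiments use: a ~1,000-variant single
patient with ~200 decoys (filter equivalence); a 100 kb genome scanned
per-basepair (atlas oracle); a 1.9 Gb uniform-placement cohort at rates
2 / 4 / 1.5 / 3 mut/Mb with ≥ 5,000 mutations per sample (burden
recovery, ≥ 95% of sample×region cells within 3 binomial SE); 2,000
mutations from a (0.6, 0.3, 0.1) three-signature mixture (refit within
±0.05, reconstruction cosine ≥ 0.95); 500 replicates of 1,000 uniform
nulls + 50 Beta(1,50) signals (FDR calibration); and 200 null genes at
B = 10,000 shuffles (adjusted-P calibration, ~5% below α = 0.05).

## Known limitations

* The promoter set is a TSS-window proxy, not an annotation-derived
  catalog; footprints (hence promoter burden) shift with the chosen
  half-width.
* Presence/absence is a read-count rule; low-coverage samples can in
  principle drop a clonal variant to subclonal. The generator does not
  produce such dropout (present samples are forced to ≥ 1 read), so
  clonality accuracy on synthetic data is exact rather than the ≥ 99%
  one would expect with binomial dropout at depth ≥ 20.
* The permutation null preserves the per-gene mutant count but not
  per-sample mutation burden; samples with many enhancer mutations are
  not over-represented in the reshuffled mutant sets.
* The rank-sum test assumes exchangeability of samples across patients;
  within-patient correlation of expression is ignored (multi-region
  samples of one patient are treated as independent).
* The synthetic signature catalog supports recovery experiments but not
  etiological interpretation; swap in a reference catalog for real use.
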