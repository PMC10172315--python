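# Methods

## The codon optimality score

A silent mutation replaces a sense codon with a synonymous sense codon.
Its codon optimality score is the difference of the two codons' usage
frequencies, `f(alt) − f(ref)`, in units of occurrences per 1,000
triplets. The vendored human table carries the standard published
per-1,000 frequencies (e.g. GGC 22.2, GGT 10.8, CAG 34.2, CAA 12.3), so
a GGC→GGT mutation scores −11.4 and CAG→CAA scores −21.9. The score is
antisymmetric by construction and bounded by the table's frequency range
(±39.6 − 0.8 on the human table, tighter within synonym families).
Substitutions creating or destroying a stop codon are not scoreable
under a translation-centric metric and are flagged rather than scored.

Score groups use fixed cuts: low (score < −10), mid (−10 ≤ score < 10),
high (score ≥ 10); both boundaries follow the quoted conventions exactly
(−10 is mid, +10 is high). Zero-score mutations are classed "neutral"
in the optimality direction (the positive/negative dichotomy leaves them
undefined) and fall in the mid group.

**Median table frequency.** The reference median of 15.1 is reproduced
by the median over all 64 codons of the vendored table; the median over
the 61 sense codons alone is 15.2. `median_frequency()` therefore
defaults to the 64-codon median, with `sense_only=True` available.

## Coordinates and codon resolution

CDS positions are 1-based (HGVS `c.` convention); codon *i* covers bases
3(i−1)+1..3i and the within-codon offset is 1–3. The MAF reader accepts
an `HGVSc` column (`c.123C>T`) or explicit
`CDS_Position`/`Reference_Allele`/`Tumor_Seq_Allele2` columns; rows
without a transcript, with ambiguous (non-ACGT) alleles, or with
unparseable coordinates are dropped and counted in the log. A record's
reference base must match the CDS at its position; a mismatch is a
data-integrity error (strict by default). One transcript per gene is
assumed — the transcript named in the record — with no canonical-
transcript inference. A genomic-coordinate path (CDS intervals from a
GTF, strand-aware position mapping) is provided for real data; the
synthetic path is CDS-coordinate based.

## Context analysis

The context of a mutation is up to *k* codons on each side of the
mutated codon (k ∈ {1, 5, 10}), truncated at CDS boundaries. The
terminal stop codon is never counted in downstream context, because
usage frequencies are translation-centric and the stop encodes no amino
acid. The two-sided mean (`mean_both`) averages over the concatenated
codon list, not over the two side-means, which differ when one side is
truncated. Mutations with empty context at a given k are excluded from
that k's analysis with a logged count.

Context groups are quartile-based: low = below the empirical 25th
percentile, high = above the 75th, mid = the rest. Percentiles are
linear-interpolation empirical quantiles; values tied with a cut go to
mid, so group labels are deterministic. Within the low and high groups
the context–score relation is summarized by Spearman correlation
(robust to the skewed frequency scale; Pearson is available by flag).

## Timing and conservation

Timing labels are consumed from a MutationTimeR-style table. The four
raw classes map onto a coarse dichotomy: early clonal and clonal →
"early"; late clonal and subclonal → "late". Score distributions per
raw class are compared with all pairwise two-sided Wilcoxon tests,
BH-adjusted across the pairs.

Conservation tracks are per-position score accessors (TSV keyed by
sequence and 1-based position, or bigWig for genomic data); missing
positions are reported missing, never zero. The control is 100,000
positions drawn uniformly **with replacement** over all CDS bases
(sampling with replacement is the simplest reading of random base
selection and scales to small synthetic CDS sets; mutated positions are
not excluded). The control sampler is seeded and bit-reproducible.
Pairwise Wilcoxon tests among {low, mid, high, control} are reported
raw and BH-adjusted.

## Candidate screen

The screen follows a fixed funnel, with the count after every step
logged and written to `funnel.json`:

1. scored silent mutations;
2. variants recurring in ≥ 3 distinct samples, cancer types pooled
   (variant identity = transcript, CDS position, ref, alt — plus gene
   for reporting);
3. |score| ≥ 10 (boundary included);
4. splicing-element overlap flags (BED half-open intervals; flagged
   variants are reported, not removed);
5. per cancer type in which the variant again recurs in ≥ 3 samples: a
   two-sided Wilcoxon test of the gene's log10(TPM + 0.01) between
   mutated and non-mutated samples of that type, plus the requirement
   that the type's mean log10 TPM ≥ 1 (computed over **all** samples of
   the type, mutated and wild-type — the sample set for this filter was
   an open choice);
6. BH adjustment over all tested (variant, cancer type) pairs as one
   family (per-cancer-type families available by option), passing at
   FDR < 0.25;
7. co-occurrence checks: whether every carrier of the silent variant
   also carries a missense/nonsense mutation in the same gene, and
   whether any such co-occurring variant is itself recurrent.

The pseudocount 0.01 in the log transform admits zero TPM values and is
configurable; it is two orders of magnitude below the expression filter
cut, so it does not move genes across the ≥ 1 boundary in practice.

## Gene-level analyses

Per-gene central scores default to the **median** of the gene's silent
mutation scores (mean available via `center="mean"`; the median is
robust to a single outlier mutation). For functional (tail) analyses
only genes with ≥ 5 mutations are summarized by default. Tail cuts are
the 5%/95% empirical quantiles with ties included (inclusive cuts keep
the selection deterministic; tails can exceed ⌈0.05 n⌉ under ties).
Gene-set contrasts compare each curated set's mutation-score multiset
against all scored silent mutations with two-sided Wilcoxon tests,
BH-adjusted over the sets. Tail genes are stratified by median
log10(TPM) across all samples (cut at 1, boundary inclusive) and by
majority coarse timing of their silent mutations, with ties going to
"late" (the conservative choice given that late mutations are the
subclonal-enriched class); genes without expression or timing data fall
into an "unknown" stratum and are counted.

## The synthetic cohort generator

The generator emulates the statistical structure of the real inputs at
desk scale; one `numpy.random.Generator` drives everything, and a fixed
seed yields byte-identical files.

**Coding sequences.** Each gene gets one transcript: ATG, 98–398
internal codons (uniform in the configured range, default 100–400 total
codons — around the human median CDS length), one stop, no internal
stops. Amino acids are drawn proportionally to their total usage
frequency; the codon within a family is drawn with probability
∝ f^T, where T is `codon_temperature` (0 = uniform synonymous usage,
1 = table-proportional, the default, giving human-like codon bias).

**Cohort.** Per-sample mutation counts are Poisson (default mean 100);
each mutation is silent with probability 0.3 (matching the observed
silent:missense balance of somatic exome cohorts) and missense
otherwise; timing classes are drawn from a default mix of 25% early
clonal, 15% late clonal, 40% clonal, 20% subclonal (a plausible clonal-
dominant mix; the analyses only depend on the classes being populated).
Silent substitutions are drawn from the enumerated pool of all
synonymous single-base substitutions in the CDS set. Timing score
shifts are planted by exponential tilting of that discrete pool: the
tilt parameter is calibrated numerically (Brent root-finding) so the
tilted pool mean moves by exactly the configured per-1,000 amount;
truth records the realized, not the target, scores, because the
substitution graph is discrete and a continuous target distribution is
unreachable. Score–context coupling multiplies the sampling weight by
exp(c · z_score · z_context), where z are pool-standardized values and
c is the coupling (negative c places non-optimal substitutions in
high-frequency contexts).

**Expression.** Per-gene baseline log10 TPM is Normal(1.5, 0.5) — most
genes clear the screen's expression filter, as expressed genes do —
with Normal(0, 0.3) per-sample noise. Causal genes (the genes with the
most silent-mutated samples, default 10) shift by ±0.5 log10 in their
mutated samples, signed by the mutation score (non-optimal down,
optimal up).

**Conservation.** Background positions get clipped-Normal mid-range
values; silent-mutated positions decrease linearly with the
standardized planted score, emulating the negative score–conservation
association.

**What the generator does not emulate:** mutational signatures and
trinucleotide context biases, copy-number structure, transcript
isoform choice, correlated expression programs, and batch effects.
Passing recovery tests therefore shows the pipeline's statistical
machinery is correct and well-calibrated at the planted effect sizes —
not that those effect sizes, or the generator's independence
assumptions, hold in real tumor data.

## Validation studies and problem sizes

`silopt.validation` (used by the test suite and `scripts/acceptance.py`)
re-derives the package's guarantees from scratch:

- codon-table lookups and the 64-codon median against the reference
  values; score antisymmetry/zero-identity over all 1,830 sense-codon
  pairs;
- exact Wilcoxon p-values against full enumeration of group assignments
  (1,000 random untied samples with combined n ≤ 8);
- BH against an independently coded closed-form step-up (100 random
  vectors) and mean realized false-discovery proportion at level 0.25
  on mixtures of 100 strong signals + 9,900 null uniforms × 100
  replicates (the mixture design estimates the FDR guarantee with low
  variance, unlike an all-null design where the per-replicate FDP is
  Bernoulli);
- planted-effect recovery: a +5 subclonal shift at 500 mutations/class,
  100 replicates (success = correct median ordering and BH-adjusted
  p < 0.05 on every subclonal contrast); a −0.5 score–context coupling
  at 2,000 mutations, 100 replicates (success = high-context median
  below low-context median);
- candidate screen performance on 100 seeded cohorts of 1,000 genes ×
  300 samples with 10 causal genes (0.5 log10 shift, 20 mutated samples
  each) and 190 null recurrent genes: sensitivity and empirical FDR at
  the 0.25 threshold;
- the exact round trip: simulator → MAF → reader → codon resolution →
  scoring reproduces every planted score bit-exactly (~1,400 silent
  mutations per run).

These sizes keep the full validation under a few minutes on one core
while leaving the Monte-Carlo error of every rate well below the margin
it is compared against.

## Known limitations

- Single-nucleotide substitutions only; indels and MNVs have no codon
  pair under this score and are out of scope.
- One designated transcript per gene; no canonical-transcript logic.
- The Wilcoxon exact/asymptotic switch (exact when combined n ≤ 12 and
  untied) reproduces distributional behavior, not any particular
  statistics environment bit-for-bit.
- The per-cancer-type "median ratio" summaries are medians of
  per-sample ratios; pooled-total ratios are a configuration switch.
- GO enrichment is out of scope; the gene-level stage exports ranked
  gene lists for external enrichment tools.
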