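# silopt

Codon-optimality analysis of silent somatic mutations in tumor cohorts.

Silent (synonymous) mutations change a codon without changing the encoded
amino acid, but synonymous codons are not used equally: common codons are
translated faster and stabilize mRNA, rare codons slow ribosomes and
destabilize it. A silent mutation can therefore still matter, by moving a
gene toward rarer or commoner codons. `silopt` quantifies this for somatic
mutation cohorts (MAF files, e.g. TCGA-style) with the **codon optimality
score**

```
score = f(alt codon) − f(ref codon)
```

where *f* is the codon's usage frequency per 1,000 triplets from a human
codon usage table (vendored with the package). Mutations with positive
scores create commoner ("optimal") codons, negative scores rarer
("non-optimal") ones; scores are binned into low (< −10), mid (≥ −10 and
< 10) and high (≥ 10) groups.

On top of the score the package implements the downstream cohort analyses:

- **Cohort summaries** — per-sample silent/missense counts and ratios,
  per-amino-acid and per-codon mutation counts, score distributions,
  germline allele-frequency stratification (≥ 0.01 vs < 0.01).
- **Codon context** — mean codon frequency of the ±1/±5/±10 codons around
  each mutated codon, quartile context groups, and the context–score
  association (Wilcoxon contrasts, Spearman correlations).
- **Clonal timing** — MutationTimeR-style labels (early clonal, late
  clonal, clonal, subclonal; coarse early/late mapping) and per-class
  score contrasts.
- **Conservation** — PhastCons/PhyloP-style per-base tracks compared
  between score groups and a control of 100,000 positions sampled from
  the coding sequence.
- **Candidate screen** — recurrent silent mutations (≥ 3 samples),
  |score| ≥ 10, splicing-element flags, per-cancer-type Wilcoxon tests of
  gene expression (log10 TPM) in mutated vs wild-type samples, mean
  log10 TPM ≥ 1 filter, Benjamini–Hochberg FDR < 0.25, and
  missense/nonsense co-occurrence checks.
- **Gene level** — per-gene central scores, top/bottom 5% tails, curated
  gene-set contrasts (essential genes / oncogenes / tumor suppressors),
  and expression/timing stratification of the tail genes.
- **Synthetic cohorts** — a seed-reproducible generator of codon-biased
  CDSs, MAF cohorts with planted timing/context score effects,
  expression matrices with planted causal genes, and conservation
  tracks, used to validate every stage.

Statistics follow the conventions of the underlying analyses: two-sided
Wilcoxon rank-sum tests (exact for small untied samples), BH adjustment,
Spearman correlation.

## Worked example

```python
from silopt import human_codon_usage, score_mutation, SimulationConfig
from silopt.simulate import simulate_cds, simulate_cohort
from silopt.evolution import compare_scores_by_timing

table = human_codon_usage()
score_mutation("GGC", "GGT", table)   # -11.4  (22.2 -> 10.8: a glycine
                                      #  codon becomes much rarer)
table.median_frequency()              # 15.1   (median of the 64 codons)

# simulate a cohort in which subclonal mutations have scores shifted +5
config = SimulationConfig(seed=42, n_genes=50, n_samples=80,
                          mutations_per_sample=80,
                          score_shift_by_timing={"subclonal": 5.0})
rng = config.rng()
cds, genes = simulate_cds(config, rng=rng)
maf, timing, truth = simulate_cohort(config, cds, genes, rng=rng)
report = compare_scores_by_timing(truth[truth.variant_class == "silent"])
print(report["summary"].round(2))
```

```
                n  median  mean
timing_raw
early_clonal  481   -2.70 -2.80
late_clonal   300   -3.55 -3.97
clonal_NA     766   -2.90 -3.32
subclonal     329    0.60  1.34
```

The subclonal class sits ~4–5 score units above the clonal classes — the
planted shift — and the pairwise contrasts (`report["contrasts"]`) give
BH-adjusted p < 10⁻⁴ for every subclonal comparison, while the contrasts
among unshifted classes stay non-significant.

The same analyses run from the shell:

```bash
silopt simulate --seed 1 --out sim/
silopt run-all --maf sim/cohort.maf --cds-fasta sim/cds.fasta \
    --timing sim/timing.tsv --expression sim/expression.tsv \
    --sample-annotation sim/samples.tsv \
    --conservation-track sim/conservation.tsv --seed 1 --out run/
```

`run/` then contains the scored mutation table, the per-figure summary
TSVs, the candidate table and `funnel.json` with the count at every
filter step.

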