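# vdjnmd

Simulation and statistics for the clearance of out-of-frame antigen-receptor
transcripts by nonsense-mediated decay (NMD).

## The problem

V(D)J recombination assembles the second exon of antigen-receptor genes
imprecisely: random nucleotide loss and gain at the junction shifts the
reading frame in two of the three outcomes, creating premature termination
codons (PTCs) in the constant region. Mammalian NMD can destroy such
transcripts through an exon-junction-complex (EJC)-dependent pathway —
which requires an exon–exon junction more than ~50–55 nt downstream of the
PTC, i.e. an intron downstream of the PTC in the gene — or through an
intron-independent "fail-safe" pathway sensing distance to the poly(A)
tract.

This package reconstructs, as tested simulation-plus-statistics code, the
computational side of an experiment that separates these routes at a
T-cell-receptor-beta-like locus using two engineered alleles:

* **A** (intron-bearing): six exons; frameshift PTCs fall in the third of
  six exons, with three introns downstream — EJC-competent;
* **F** (exon-fused): the four constant exons fused into one, so the same
  PTCs (identical spliced mRNA, identical 0.7 kb distance to the poly(A)
  tract) fall in the final exon — fail-safe only.

It provides: paired allele/transcript models with splicing and exon fusion
(`gene_models`); a V(D)J junction simulator with an allelic-exclusion
population model (`vdj_sim`); a PTC/EJC annotator (`ptc_annotate`); a
decay-pool sampler emitting FASTA pools with truth tables (`decay_pools`);
fold-reduction, binomial and Monte Carlo statistics (`ptc_stats`); and a
CLI pipeline (`vdjnmd`).

## The statistics

For a genotype g with DNA and RNA pool counts (n⁺, n⁻), the odds-normalised
fold reduction is

    F_g = (n⁺/n⁻)_DNA ÷ (n⁺/n⁻)_RNA ,

which equals the inverse of the per-molecule survival factor s under the
decay model (bootstrap 95% CI). Each RNA pool is tested against the DNA
PTC⁺ fraction with an exact two-sided binomial test, and the two genotypes
are compared with a seed-controlled Monte Carlo test of
Δ = log F_A − log F_F under a pooled-survival null. Allelic exclusion caps
the fraction of surviving cells with two complete VDJ rearrangements at
(1 − p)/(2 − p) = 40% for per-junction productive probability p = 1/3.

## Worked example

Run the full synthetic experiment (default survival factors s_A = 1/12,
s_F = 1/3; 3,000 cells per genotype, 2,000 molecules per pool):

```
vdjnmd run --seed 1 --out demo --quiet
```

which prints (abridged):

```
genotype molecule  fold_reduction   ci_low   ci_high  lower_bound  p_binomial_vs_dna
       A pre_mrna        0.973888 0.851311  1.117119        False       5.885726e-01
       A     mrna       11.043942 8.664077 14.549753        False      7.943133e-195
       F pre_mrna        0.970954 0.846532  1.114574        False       5.507872e-01
       F     mrna        2.693160 2.291392  3.181595        False       9.507987e-62
monte carlo A-vs-F (mRNA fold reduction): delta_logF = 1.4112, p = 9.999e-05
```

Reading it: pre-mRNA pools mirror genomic DNA (fold ≈ 1, binomial p ≫ 0.05
— decay acts after splicing), while PTC⁺ mature mRNA is depleted ~12-fold
on the intron-bearing allele but only ~3-fold on the exon-fused allele
(the CIs bracket 1/s_A = 12 and 1/s_F = 3), and the Monte Carlo test
rejects equality of the two fold reductions. The run directory contains
every intermediate artifact: allele models and exon tables, per-cell
population TSVs, pool FASTAs with truth tables, annotation TSVs, the count
table and the report. Stage subcommands (`models`, `simulate`, `pools`,
`annotate`, `counts`, `stats`) re-run any step from the previous step's
files and reproduce `run` bit-for-bit given the same seed.

Library use mirrors the CLI:

```python
import numpy as np
from vdjnmd import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(master_seed=1))
print(report.text())
```

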