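# codonshift

Quantify shifts in natural selection on synonymous codon usage between
protein regions with an explicit population-genetics model.

The codon-choice model is a selection–mutation–drift multinomial logit: for
an amino acid with `n_aa` synonymous codons, the probability of codon *i* in
gene *g* is

```
p_i = exp(-dM_i - deta_i * phi_g) / sum_j exp(-dM_j - deta_j * phi_g)
```

where `dM` is the log mutation-rate ratio and `deta` the selection
coefficient (s·Ne units in a gene of average expression), both relative to a
per-family reference codon, and `phi_g` is the gene's protein production
rate (scaled so the genome mean is 1). Serine is split into its TCN and
AGC/AGT families, giving 19 synonymous families over 59 sense codons and 40
free parameters per parameter class.

## What's included

| module | purpose |
| --- | --- |
| `codonshift.codon_core` | genetic-code bookkeeping, codon probabilities, likelihood, counting |
| `codonshift.synthetic_data` | forward simulator: lognormal expression, segment label grammars, sign-flipped selection sites, replicate null genomes |
| `codonshift.region_partition` | DSSP/disorder label tracks, 35-codon 5' exclusion, grouping schemes, termini and positions-2–3 splits |
| `codonshift.fit_mcmc` | adaptive random-walk Metropolis fits (full genome-wide and region selection-only), DIC and model comparison |
| `codonshift.selection_compare` | favored-codon rescaling, Deming regression, interval-based shift calls, Spearman correlation, exact binomial false-positive audit |
| `codonshift.position_enrichment` | per-position non-optimal-codon odds ratios in helices and their simulated null distributions |
| `codonshift.workflow_io` | FASTA/TSV/CSV I/O and the `codonshift` CLI |

## CLI

```bash
# simulate an annotated genome (writes FASTA, annotation TSV, truth tables)
codonshift simulate --n-genes 100 --mean-length 300 --seed 1 --out-dir out/sim

# partition codons into region groups (first 35 codons excluded by default)
codonshift partition --fasta out/sim/cds.fasta \
    --annotations out/sim/annotations.tsv --scheme separate --out-dir out/part

# fit selection coefficients for one group, mutation bias and phi fixed
codonshift fit --counts out/part/counts_H.csv \
    --params out/sim/truth_params.csv --phi out/sim/truth_phi.csv \
    --seed 2 --out-dir out/fit_H

# compare two region fits (Deming slope, shift calls, binomial audit)
codonshift compare --fit-a out/fit_H/draws.csv --fit-b out/fit_E/draws.csv \
    --null-fit out/fit_null/draws.csv --out-dir out/cmp

# end-to-end synthetic analysis
codonshift pipeline --flip-fraction 0.5 --seed 3 --out-dir out/pipe
```

`codonshift termini` builds termini/core label tracks and
`codonshift positions` runs the per-position odds-ratio analysis with its
simulated null. Every command writes a `manifest.json` (inputs, seed,
version, wall time) into its output directory.

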