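# xscnd — cross-species array-CGH copy-number divergence calling

`xscnd` detects gene copy-number divergence between a reference species
and heterologous relatives from genomic-DNA hybridizations on the
reference species' short-oligonucleotide (25-mer) expression array —
the comparative-genomic-hybridization setting used to screen, for
example, *Arabidopsis* relatives against an *A. thaliana* GeneChip.

The obstacle in any cross-species hybridization is sequence divergence:
a heterologous target carrying mismatches against its 25-mer probe
hybridizes less efficiently, so its signal drops for reasons that have
nothing to do with copy number. `xscnd` corrects this bias globally
before calling copy-number expanded (CNE) and reduced (CNR) genes.

## The model

Each of the n = 25 probe positions either matches the heterologous
target or not, so the per-probe mismatch count K is Binomial(n, p),
with p the average per-base divergence between the species (default
p = 0.06, i.e. 94% identity). On a curated reference set of
single-copy genes with known heterologous sequence, the incremental
correction factor for mismatch class k is the arithmetic mean of
home/heterologous intensity ratios,

    S_k = (1/N_k) · Σ_i  H_ik / I_ik ,

and the species-specific global scaling factor weights these by the
binomial probability of each class, truncated at k = 4:

    S = Σ_{k=0..4}  S_k · P_n(k) .

Every heterologous intensity is multiplied by S; replicate-paired probe
log2 ratios then go through a probe-blocked linear test with
empirical-Bayes moderated variance, Benjamini–Hochberg correction, and
threshold classification: CNE at log2 ratio ≥ +1 with adjusted
p ≤ 0.1, CNR at ≤ −1. Downstream modules score calls against truth
sets, run Fisher-exact functional over-representation analysis, scan
chromosomes with 20-kb windows for large segmental events, and
re-implement two earlier cross-species callers (conserved-gene loess
and ΔG37-affinity scaling) for comparison.

## Worked example

The built-in generator plants known copy states (5% doubled genes, 5%
halved genes, mismatch-attenuated heterologous signal, two replicates):

```python
from xscnd import (SimulationConfig, simulate_dataset,
                   make_reference_subset, run_pipeline, recovery_metrics)

ds = simulate_dataset(SimulationConfig(seed=1, n_genes=500))
ref = make_reference_subset(ds, n_genes=100)
res = run_pipeline(
    ds.intensities, ds.mismatches, ref.probeset_ids,
    species_home="home", species_het="het",
    mask_patterns=list(ds.control_probesets), gene_map=ds.gene_map,
)
print(res.factors.per_k.round(3))
print("S =", round(res.factors.S, 3))
rm = recovery_metrics(res.calls, ds.truth, "CNE")
print(f"CNE detection sensitivity {rm.sensitivity_detection:.1f}%, "
      f"precision {rm.precision_class:.1f}%, FPR {rm.fpr_class:.2f}%")
```

prints

```
     S_k  N_k
0  0.912  225
1  1.544  400
2  1.678  285
3  1.887  137
4  1.937   34
S = 1.482
CNE detection sensitivity 100.0%, precision 100.0%, FPR 0.00%
```

Reading the output: probes whose targets carry one mismatch lose about
a third of their signal (S_1 ≈ 1.5 means the home signal is ~1.5× the
heterologous one), the loss grows slowly with further mismatches, and
the binomial-weighted global factor S ≈ 1.48 rescales the heterologous
arrays. With the correction in place every planted doubling is detected
and no single-copy gene is miscalled.

The same flow is available from the shell:

```sh
xscnd simulate --seed 1 --out data/
xscnd run --intensities data/intensities.tsv --mismatches data/mismatches.tsv \
          --reference ref.txt --home home --het het --out calls.tsv
xscnd validate --calls calls.tsv --truth data/truth.tsv
xscnd enrich --calls calls.tsv --categories data/categories.tsv --out ora.tsv
xscnd segments --calls calls.tsv --genes-bed data/genes.bed \
               --chrom-lengths data/chrom_lengths.tsv --out segments.bed
```

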