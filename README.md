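# ptml — predicted total mutation load from targeted gene panels

Tumor mutation load (the count of somatic, non-synonymous, exonic mutations
in a tumor exome) predicts clinical benefit from immune checkpoint blockade,
but whole-exome sequencing (WES) is expensive and bioinformatically heavy.
`ptml` estimates the total load from the mutation status of a small clinical
NGS gene panel, for oncologists and genomics analysts who already run such
panels to select targeted therapies.

## The method

Given a WES derivation cohort and a gene panel of *n* genes, each panel gene
*k* receives an **unadjusted mutation value**: the lowest actual total
mutation load (ATML) among cohort samples carrying a mutation in *k*.
Recurrent driver genes (BRAF-like) appear even in lightly mutated tumors and
therefore earn small values; genes only ever hit as passengers in
hypermutated tumors earn large ones. Per-sample sums of unadjusted values
are regressed on the ATML, and each gene's value is divided by the slope and
rounded, giving the **adjusted mutation value**. A panel-sequenced tumor's
predicted total mutation load is then

```
PTML = Σ_{k=1..n} RND( MIN(ATML among carriers of gene k) / slope ) × m_k
```

where `m_k` is the number of mutations observed in gene *k* (0 for unmutated
genes). Tumors are dichotomized at **PTML ≤ 100 (low) vs > 100 (high)**;
a PTML of zero strongly indicates a true load ≤ 100. The low class is
associated with worse immunotherapy outcome, assessed by Kaplan–Meier
curves, median survival (with the convention that the median is *undefined*
when survival never reaches 50% within follow-up), and the log-rank test.

The package also computes per-sample substitution-class fractions (C>T as a
UV proxy, C>A as a smoking proxy) and ships a synthetic cohort simulator so
the whole pipeline runs and is tested without any external downloads.

## Worked example

```
ptml simulate --out-maf cohort.maf --out-truth truth.tsv --out-outcomes outcomes.tsv
python -c "from ptml.simulate import *; print('\n'.join(panel_gene_names(PanelSpec())))" > panel.txt
ptml derive --maf cohort.maf --panel panel.txt --out weights.tsv --label sim
# -> derived 170 gene weights (0 excluded), slope=3.8060, r2=0.9513 over 300 samples
ptml score --weights weights.tsv --calls cohort.maf --out scores.tsv
# -> scored 300 samples; 105 low (PTML <= 100)
ptml survival --scores scores.tsv --outcomes outcomes.tsv --out report.json
# -> log-rank chi2=36.020, p=1.953e-09
```

The `derive` line reports the regression calibration: the slope (≈3.8) says
a sample's sum of raw min-carrier values overestimates its ATML about
3.8-fold before adjustment, and r²≈0.95 says the panel sum tracks the exome
load tightly in the derivation cohort. The `survival` report shows that
low-PTML patients (here simulated with a 2.5-fold hazard) separate sharply
from high-PTML patients (log-rank p ≈ 2e-9).

The same `ptml derive` command applies unchanged to a real TCGA MAF plus a
clinical panel list (one HUGO symbol per line).

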