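# methage

Composition-aware analysis of DNA-methylation signals in whole blood, for
studies of aging and Alzheimer's disease (AD).

## The problem

Epigenome-wide association studies of peripheral whole blood (PWB) routinely
find CpG sites whose methylation (beta value) correlates with age, or differs
between AD patients and controls. But whole blood is a mixture of leukocytes,
and the myeloid:lymphoid ratio itself increases with age and in AD. A bulk
"age-associated CpG" can therefore reflect either

* an **intrinsic** methylation change inside the cells, or
* a **composition shift**: the probe is differentially methylated between
  myeloid and lymphoid cells, and the mixture is drifting.

`methage` implements a statistical framework that separates the two, plus all
the machinery around it: beta-value preprocessing, per-CpG age regression with
cross-dataset integration, rank-product case/control differential
methylation, reference-based leukocyte deconvolution, concordance/overlap
statistics, and Fisher's-exact gene-set enrichment. A synthetic-data
generator with full ground truth (planted age slopes, AD effects,
lineage-differential probes, an age-drifting mixture) makes every stage
verifiable at desk scale.

## Core statistics

* **Beta value**: β = max(M, 0) / (M + U + 100) from methylated/unmethylated
  intensities; QC removes samples with >10% missing values, imputes the rest
  by nearest-probe-row kNN (k = 1), iteratively drops arrays whose mean
  inter-array Pearson correlation lies >2 SD below the mean (3 iterations),
  and restricts to platform-shared autosomal probes.
* **Age-CpGs**: per-probe OLS of β on age (+ covariates), BH-FDR < 0.05
  within each dataset; integrated across datasets (FDR-significant in one,
  nominally significant in another, no sign conflicts).
* **AD-CpGs**: two-class rank product over all n₁×n₂ between-class sample
  pairs, ranking per-pair β differences; significance by within-array
  probe-label permutations, with pfp (percentage of false prediction) as the
  FDR analogue.
* **ML-CpGs**: Welch t-test between myeloid and lymphoid purified profiles,
  BH-FDR < 0.05, keeping the signed myeloid−lymphoid mean difference.
* **Deconvolution**: nonnegative least squares A·X ≈ B on the 500
  most-variable marker loci of the reference panel; subtype weights are
  aggregated to myeloid/lymphoid fractions and rank-correlated with age.
* **Concordance**: for two signed CpG lists sharing k probes of which s agree
  in direction, the concordance rate is s/k and its significance the upper
  binomial tail P(X ≥ s), X ~ Bin(k, p_e = 0.5); list overlaps are tested
  against the analyzed-probe universe with the hypergeometric upper tail.
  Probes concordant with the composition shift are removed before asking
  whether age- and AD-lists share intrinsically altered CpGs.

## Worked example

```python
from methage import pipeline

config = pipeline.PipelineConfig().with_seed(1)
report = pipeline.run_full_pipeline(config)
```

Printing the headline fields of `report` gives:

```
analyzed probes            : 1840
integrated Age-CpGs        : 385
AD-CpGs (rank product)     : 99
ML-CpGs (myeloid vs lymph) : 208
Spearman r (myeloid ~ age) : +0.901 (p=3.36e-40)
Age-CpG vs ML concordance  : 200/200 = 100.0%
filtered Age x AD overlap  : 24 of 185 x 54 (p=2.67e-11)
AD-Age concordance         : 22/24 = 91.7% (p=1.79e-05)
```

Reading: the estimated myeloid fraction rises with age (r = +0.90), so the
200 Age-CpGs that coincide with lineage-differential probes agree perfectly
with the composition shift — they are composition-driven. After removing
them, the remaining age and AD lists still overlap 24 probes, far beyond
chance (hypergeometric p ≈ 3×10⁻¹¹), and 22/24 of those change in the same
direction in aging and AD: the signature of a shared intrinsic alteration,
which is exactly how the generator planted them.

The same analysis is available from the shell, stage by stage or end to end:

```bash
methage run-all --out outdir/ --seed 1
methage simulate --seed 1 --out sim/
methage preprocess --beta sim/beta.tsv --probes sim/probes.csv --out prep/
```

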