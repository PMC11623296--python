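# tdratio

Transcriptomic-distance analysis of tumor organotropism: are primary and
metastatic tumors transcriptionally closer to their normal **origin tissue
(OT)** or to their **metastatic target tissue (TT)**?

`tdratio` implements the full analysis as a tested, reusable Python
pipeline: whole-transcriptome and pathway-level distance ratios,
organotropism specificity scoring, tumor-purity residualization,
empirical random-gene-set nulls, and gene-set enrichment of
metastatic-vs-primary expression shifts.  A synthetic-cohort generator
produces data with the statistical structure the analysis assumes, so
the entire pipeline runs — and is validated — without any downloads.

## The statistics at the core

For a tumor sample *X* and a normal tissue *Y*, the **transcriptomic
distance** TD(*X*, *Y*) is the Euclidean distance between the
log2-transformed, z-score-standardized expression vector of *X* and the
per-gene median (mean for sparse single-cell data) profile of *Y*.
The **TD ratio**

> TD ratio(*X*) = TD(*X*, OT) / TD(*X*, TT)

is > 1 when the sample is closer to its target tissue and < 1 when it is
closer to its origin tissue.  On top of this the package provides:

- **Normalized TD ratio** TD(OT, TT)/TD(*X*, TT) and the **specificity
  score**: the number of decoy target tissues against which the true
  TT's normalized ratios are significantly higher (one-sided Wilcoxon
  signed-rank, BH FDR < 0.1).
- **PMT score** ED(met, paired primary)/ED(met, TT), asking whether a
  metastasis has drifted closer to its target tissue than to its own
  primary tumor.
- **Δ pathway-specific ratios**: the group-median ratio restricted to a
  pathway's genes divided by the all-genes median, with empirical
  P = (r + 1)/(n + 1) from random same-size gene sets, folded two-sided
  via min(P, 1 − P), and BH FDR.
- **Purity residualization**: when TD ratios correlate with tumor purity
  (Spearman p < 0.05 in either tumor class), ratios are replaced by the
  residuals of the linear model `ratio ~ purity`.
- **Pre-ranked gene-set enrichment** on log2 geometric-mean fold changes
  (metastatic / primary), plus a rank-ECDF single-sample activity score
  for unpaired cohorts.

## Worked example

```python
from tdratio import build_references, cohort_td_ratios, summarize_groups
from tdratio.simulate import CohortSimulator, SimulationConfig

sim = CohortSimulator(SimulationConfig(n_genes=1000, n_patients=20, seed=1))
normals, normal_ann = sim.generate_reference_cohort()
tumors, tumor_ann = sim.generate_tumor_cohort("colon", "liver")

refs = build_references(normals, normal_ann)          # per-tissue medians
td = cohort_td_ratios(tumors, tumor_ann, refs)        # per-sample TD ratios
print(td.groupby("role")["ratio"].median())
print(summarize_groups(td)[["test", "p", "direction"]])
```

prints

```
role
metastatic    1.022752
primary       0.541204
Name: ratio, dtype: float64
          test             p           direction
0  signed_rank  9.536743e-07  metastatic_greater
```

Primary tumors (mixture weight 0.2 toward the target tissue) sit well on
the origin side (median ratio ≈ 0.54); their paired metastases (weight
0.5) have drifted to equipoise (≈ 1.02), and the one-sided signed-rank
test across the 20 pairs confirms the metastatic ratios are systematically
higher — the organotropic shift the pipeline is built to detect.

The same analysis is available from the shell:

```bash
tdratio simulate --out bundle/ --seed 1
tdratio run --config run.yaml --out results/
```

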