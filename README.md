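# mirmeta

Random-effects meta-analysis of miRNA differential expression for drug
resistance in HER2+ breast cancer, with downstream integration of validated
miRNA→mRNA targets, over-representation analysis, protein-interaction hub
ranking and Kaplan–Meier survival.

## Who this is for

Bioinformaticians who want to combine several small two-group (resistant vs
control) expression studies from different platforms into one ranked list of
differentially expressed miRNAs (DEMs), and then follow the signal through to
candidate target genes and their clinical relevance. Because public
multi-study data cannot be redistributed, the package ships a fully
synthetic multi-study generator with planted signal, so every stage is
testable offline and recovery can be scored against known ground truth.

## The statistics at the core

Per study, each feature gets a log2 fold change and an empirical-Bayes
moderated t statistic:

    logFC = mean(resistant) − mean(control)
    s²_post = (d₀·s₀² + df·s²) / (d₀ + df)
    t = logFC / sqrt(s²_post · (1/n₁ + 1/n₂)),   df_total = d₀ + df

with the variance prior (d₀, s₀²) estimated by the method of moments on
log s². Study-level standard errors are recovered as SE = |logFC / t|, and
per-miRNA effects are combined with the DerSimonian–Laird random-effects
model after a Cochran's Q heterogeneity test:

    w_i = 1/SE_i²,  Q = Σ w_i (ES_i − ES_fixed)²
    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))
    ES = Σ ES_i/(SE_i²+τ²) / Σ 1/(SE_i²+τ²),  z = ES/SE_meta

P-values are Benjamini–Hochberg adjusted across the feature universe
(DEMs: adj. p < 0.05; DEGs additionally |log2FC| > 1). Significant human
("hsa"-prefixed) DEMs are mapped to validated target genes and intersected
with the DEG union; the overlap is tested for gene-set over-representation
(hypergeometric upper tail, Bonferroni/BH/Holm, Cohen-kappa redundancy
grouping at 0.96), ranked for network hubs by degree, and followed up with
Kaplan–Meier curves, a log-rank test and an O/E hazard ratio
HR = (O₁/E₁)/(O₂/E₂) with 95% CI exp(ln HR ± 1.96·√(1/E₁+1/E₂)).

## Worked example

```bash
mirmeta run --seed 1 --outdir results/run1
```

runs synthetic generation, imputation, per-study differential expression,
meta-analysis, target intersection, enrichment, hub ranking and survival, and
prints (abridged):

```json
{
  "degs_per_study": {"mRNA_study_1": 65, "mRNA_study_2": 67, "mRNA_study_3": 57},
  "n_dems": 21, "n_dems_up": 8, "n_dems_down": 13,
  "n_dem_targets": 84, "n_deg_union": 94, "n_overlap": 64,
  "top_terms": [["GO:0000001", 0.0], ["hsa00013", 0.040546]],
  "top_hubs": [["GENE877", 70], ["GENE527", 13]],
  "survival": {"gene": "GENE877", "p": 3e-06, "hr": 2.14107,
               "ci_low": 1.525566, "ci_high": 3.004904}
}
```

Reading: 21 miRNAs are significant after meta-analysis and BH adjustment
(the generator planted 20 true DEMs plus nulls, so roughly one false call at
FDR 5%); their validated targets overlap the DEG union in 64 genes; the
planted enriched term GO:0000001 ranks first; the planted hub GENE877
dominates the network; and the high-expression group for that gene shows the
planted hazard ratio of about 2 (true HR = 2).

Every stage is also a library call (`mirmeta.meta.random_effects_combine`,
`mirmeta.survival.logrank_hr`, ...) and a standalone subcommand
(`mirmeta de`, `mirmeta meta`, `mirmeta targets`, `mirmeta enrich`,
`mirmeta network`, `mirmeta survival`).

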