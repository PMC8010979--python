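# methlink

Saliva co-methylation networks, module eigengenes, and bootstrap mediation
linking childhood **family emotional health (FEH)** to fronto-limbic
brain-region volumes.

## The problem

Adverse social environments in childhood leave traces in both the
peripheral epigenome and brain morphology. One analysis strategy for
cohorts with saliva MethylationEPIC arrays, structural MRI, and
questionnaire phenotypes asks whether DNA-methylation signatures
*statistically mediate* the association between a childhood
family-emotional-health score and the volumes of stress-sensitive brain
regions (hippocampus, amygdala, dorsolateral and medial prefrontal cortex,
per hemisphere). `methlink` implements that full analysis chain as a
tested, reusable Python library, together with a synthetic-cohort generator
that plants known structure so every stage can be validated end to end
without access-restricted subject data.

The pipeline stages:

1. **Preprocessing** — quantile normalization of beta values, the
   variance-stabilizing M-transform `M = log2(beta / (1 - beta))`, removal
   of X/Y-chromosome, SNP (rs) and cross-hybridizing probes, and a
   cross-tissue filter keeping only probes whose saliva signal shows a
   significant Pearson correlation (p < 0.05) with paired brain tissue.
2. **Reference-free deconvolution** — alternating constrained least squares
   on the most variable probes estimates K = 5 latent cell-type proportions
   (rows on the simplex), used downstream as covariates.
3. **Co-methylation network** — probe M-values are residualized on age,
   sex, ancestry and cell proportions; adjacency is `|Pearson r|^beta` with
   the soft power chosen by scale-free topology fit; probes are clustered
   on topological-overlap dissimilarity (1 − TOM) with average linkage and
   a static cut; each module (minimum 10 probes) is summarized by its
   eigengene (ME), the first principal component of its standardized probes.
4. **Gated association arms** — Arm A: FEH → region volume (covariates:
   age, sex, 4 ancestry components, past-year stressful-life-events score,
   total brain volume). Arm B: FEH → ME (SLE-adjusted). Arm C: ME → volume
   (Arm A covariates). Models graduate at p < 0.05; Benjamini–Hochberg
   reporting at FDR = 0.10 across each declared family.
5. **Bootstrap mediation** — for each surviving (ME, region) pair the FEH
   effect is decomposed as `IDE = a·b·Δ`, `DE = c'·Δ`, `TE = IDE + DE`
   (exactly, in every draw) under a nonparametric case-resampling bootstrap
   with percentile CIs; a mediator is *full* if DE is indistinguishable
   from 0 while IDE and TE are not, *partial* if all three are nonzero.
   Probes of fully mediating modules get the same treatment individually.
6. **Gene-set enrichment** — probe-wise FEH association (Bayesian ridge
   with an exact flat-prior/OLS mode), Šidák min-p gene scores penalizing
   probe-rich genes, rank-sum tests of 50–1000-gene sets, and a greedy
   Jaccard sweep for a non-redundant summary.

## Worked example

```python
import pandas as pd
from methlink import (CohortConfig, run_pipeline, mediate,
                      classify_mediation, proportion_mediated)

cfg = CohortConfig(seed=0)            # 98 subjects, 2000 probes, 10 planted modules
res = run_pipeline(cfg, n_boot=2000)

# which detected module carries the planted mediator (true module 1)?
truth = res.true_labels.loc[res.modules.labels.index]
hit = pd.crosstab(truth, res.modules.labels).loc[1].drop(0).idxmax()
name = res.modules.names[hit]

m = mediate(res.phenos, res.eigengenes[name], cfg.target_region,
            n_boot=10_000, seed=0)
```

Output of the run above:

```
power 5.0 | retained probes 1536 | modules 10
planted mediator module detected as: brown size 19
  IDE     -58.6 mm^3   95% CI ( -133.2,  -16.3)   p = 0.003
  DE     -169.8 mm^3   95% CI ( -364.5,   59.4)   p = 0.147
  TE     -228.4 mm^3   95% CI ( -414.2,  -23.4)   p = 0.029
classification: full
proportion mediated: 26%
FEH contrast: 29.0 (poorest) vs 70.0 (best)
```

Reading: moving from the best observed family-emotional-health score (70)
to the poorest (29) is associated with a 228 mm³ smaller right amygdala;
59 mm³ (26%) of that effect flows through the detected co-methylation
module ("brown", 19 of the 20 planted probes), whose direct-path CI spans
zero — a full statistical mediator. At this cohort scale (n = 98,
effect sizes matched to the motivating study) the mediation is detectable
but marginal, which is the realistic regime.

A stage-by-stage CLI mirrors the library
(`methlink simulate|preprocess|deconvolve|network|associate|mediate|enrich`).

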