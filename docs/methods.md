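# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations behind `methlink`. The package's purpose is to make a
saliva co-methylation mediation analysis — FEH score → module eigengene →
brain-region volume — fully testable on synthetic cohorts with planted
truth, because the subject-level data such analyses run on are access
restricted.

## Synthetic cohort model

**FEH score.** The 70-item family-history questionnaire is modelled as a
one-factor probit item-response model: subject liability `z ~ N(0, 1)`
(floored at −2.5), item probability of a "no" answer
`Phi(1.2 + 0.55·z)`, score = number of "no" answers. The three constants
were calibrated once so the score reproduces the cohort-scale moments of
the measure (mean ≈ 60, SD ≈ 8.6 on the 0–70 scale, observed minimum
around 30 at n = 98). The floor exists because the questionnaire has an
effective floor in this population; without it the model occasionally
produces scores in the single digits, which both misrepresents the measure
and creates high-leverage design points that distort bootstrap coverage.
Item-level prevalences are not identified by the published summary, so a
single threshold shared by all items is a deliberate free choice.

**SLE score.** Past-year stressful-life-events impact shares the FEH
liability: `sle = 11 + 7.6·(ρ·(−z)·sign + sqrt(1−ρ²)·ε)`, rounded and
truncated to [0, 45]. The loading ρ is the requested score correlation
(default −0.44) divided by the empirical attenuation corr(FEH, z) = 0.89,
so the *score* correlation hits the target. Correlation targets with
magnitude ≥ 0.89 are rejected as infeasible.

**Covariates and volumes.** Age ~ U(18, 22); sex ~ Bernoulli(0.69 female,
coded 1); four ancestry components ~ N(0, 0.05). Total brain volume is
drawn first (1.2 × 10⁶ ± 1.2 × 10⁵ mm³); each regional volume is its
cohort-scale mean plus a TBV component scaled for corr ≈ 0.6, Gaussian
noise at 0.8 of the regional SD, and — for the target region only — the
planted direct FEH term and the mediator-module contributions. Defaults:
`a_effect = 0.03` latent units per FEH point, `b_effect = 44` mm³ per
latent unit, `c_direct = 4.33` mm³ per FEH point. These reproduce the
magnitude regime of the motivating analysis for the right amygdala: a
total effect near −200 mm³ over the observed FEH range, roughly a quarter
of it indirect. At n = 98 such effects are *marginally* detectable by
design; tests that need high power use larger n or stronger effects
explicitly.

**Methylation.** Each planted module's probes load (loadings ±U(0.8, 1.2))
on the module latent (unit-SD noise around the FEH-driven part for
mediator modules); baselines are N(0, 2) on the M scale; small age/sex
effects plus cell-composition effects and N(0, 0.6) probe noise are added
before the inverse-logit to beta. 300 designated background probes carry
large (SD 4 on the M scale) cell-type contrasts so that — as on real
arrays — cellular composition dominates the variance ranking used to pick
deconvolution probes. Without such markers the most variable probes are
the planted modules themselves and reference-free deconvolution absorbs
module signal, destroying it during residualization. The manifest plants
X/Y/rs/cross-hybridizing probes among the background (never in modules) to
exercise the filters.

**Cross-tissue reference.** A flagged fraction of probes (default 0.8 in
the pipeline) get a reference column equal to the saliva column plus
M-scale noise; the rest are row-permuted so the pairing carries no signal,
giving a clean type-I/power decomposition for the saliva–brain filter.

What the generator does **not** emulate: probe-wise heteroscedasticity and
type-I/II chemistry differences, batch effects, genomic autocorrelation of
methylation, realistic gene-annotation topology, and any nonlinear
exposure–outcome structure. Passing tests therefore demonstrate the
correctness and calibration of the machinery under a linear, well-specified
world — not robustness to those artefacts.

## Numerical and procedural choices

* **Beta/M transform** clips to [eps, 1−eps], eps = 1e−6; round trip exact
  to 1e−10 away from the bounds.
* **Quantile normalization** maps each sample's average ranks onto the mean
  of sorted sample vectors, interpolating at tied (fractional) ranks;
  idempotent to numerical precision.
* **Deconvolution** alternates probe-wise least squares (profiles clipped
  to [0, 1]) with per-sample NNLS projected onto the simplex; stops on
  relative Frobenius improvement < 1e−6 or when a projection overshoots
  (the previous iterate is kept, so the accepted error path is
  non-increasing); 10 Dirichlet restarts by default, lowest error kept;
  components relabelled by descending mean proportion. K is fixed at 5.
* **Soft threshold**: lowest candidate power with signed adjusted R² of the
  log-binned log-log degree fit above 0.90, else the best-fitting power
  with a warning. The end-to-end pipeline restricts candidates to powers
  4–6: planted-block topology is not scale-free, so the R² criterion
  rarely triggers and the unrestricted fallback can wander to extreme
  powers that either merge (low) or dissolve (high) genuine modules;
  4–6 is the conventional range for unsigned networks at this sample size.
* **Network**: unsigned adjacency `|r|^beta` (zero diagonal), TOM
  `(l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, dissimilarity 1 − TOM,
  verified against a triple-loop oracle to 1e−10.
* **Module detection**: average linkage on 1 − TOM with a *static absolute
  cut* at height 0.98, clusters under 10 probes dissolved. An absolute cut
  is used instead of a merge-height quantile because with tight blocks plus
  diffuse background the top merge heights all crowd toward 1.0 and a
  quantile cut lands above the block joins, merging distinct modules.
  Probes are clustered in canonical (sorted) order, making labels invariant
  to input order; modules are numbered by descending size and named from a
  fixed color palette.
* **Eigengenes**: probes standardized, first left singular vector scaled to
  unit sample variance, sign fixed by positive mean correlation with the
  module's probes.
* **Mediation**: linear product-of-coefficients with no treatment–mediator
  interaction (the decomposition is exactly additive per draw);
  nonparametric case-resampling bootstrap, percentile 95% CIs, two-sided
  bootstrap p with a 1/(B+1) continuity floor; rank-deficient resamples are
  redrawn and counted. The default contrast runs from the observed FEH
  minimum (poorest) to the observed maximum, so effects read as
  worst-versus-best differences in mm³. Percentile intervals for the
  direct and total effects undercover by ~3–4 percentage points at
  n = 200 (measured 0.91 over 300 null replicates) — the expected
  first-order behaviour of percentile case-resampling intervals for
  regression coefficients; the indirect effect's null coverage is nominal
  (0.953). BCa or studentized intervals would reduce this but the
  percentile convention is kept for comparability with the standard
  mediation bootstrap.
* **Probe-wise association** (enrichment stage): FEH regressed on each
  residualized probe with SLE adjustment; slopes get independent
  N(0, 10²) priors (intercept flat) with a plug-in residual variance and
  normal posterior tails; `prior_sd=None` switches to exact OLS t-tests,
  which is the oracle-equivalence mode. Cell-heterogeneity covariates are
  *not* re-entered by default (they were already removed by
  residualization); a toggle exists because double adjustment is harmless
  but not obviously intended.
* **Gene scores**: Šidák `1 − (1 − min p)^n_probes`, penalizing probe-rich
  genes; multi-gene probes count once per gene; unannotated probes are
  dropped only here. Set test: one-sided Mann–Whitney on −log gene scores,
  in-set versus rest, size window applied after universe intersection;
  redundancy reduced by a greedy Jaccard sweep (threshold 0.5) in p order.
* **BH step-up** is shared by every stage: critical value rank/m × FDR,
  flags propagate to all p at or below the largest significant p; the
  declared family may exceed the supplied p-vector.

## Problem sizes

Tests and the acceptance script run the study at a scale chosen to keep a
laptop-class single-CPU run comfortable while preserving every structural
feature: 98 subjects, 2000 probes (10 planted 20-probe modules, 300 cell
markers), networks of ~1500 filtered probes, 1000–10,000 bootstrap draws,
and 10–300 replicate cohorts depending on the property under test. The
statistical behaviour checked (coverage, type-I rates, recovery) is
scale-free in the relevant regimes.

## Limitations

Mediation here is statistical, not causal: sequential ignorability is
assumed, no sensitivity analysis is provided, and mediators are tested one
at a time. The enrichment stage is a transparent rank-sum analog of
methylation-aware GSEA, not a reimplementation of any specific tool, and
is labelled as such in outputs. Reference-based deconvolution, dynamic
tree cutting, block-wise networks beyond ~10⁴ probes, and signed networks
are out of scope.
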