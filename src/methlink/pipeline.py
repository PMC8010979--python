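"""End-to-end orchestration of the synthetic study.

Chains every stage — cohort simulation, preprocessing, reference-free
deconvolution, co-methylation network and eigengenes, the three gated
association arms with BH control, bootstrap mediation, and gene-set
enrichment — into one call, returning all intermediate artifacts so tests
and scripts can interrogate any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from . import deconvolution as deconv
from . import enrichment as enrich
from . import mediation as med
from . import network as net
from . import preprocess as prep
from . import synthetic as syn


@dataclass
class PipelineResult:
    config: syn.CohortConfig
    phenos: pd.DataFrame
    latents: pd.DataFrame
    beta: pd.DataFrame
    manifest: pd.DataFrame
    true_labels: pd.Series
    retained_probes: pd.Index
    mixture: deconv.CellMixture
    resid: pd.DataFrame
    soft_threshold: net.SoftThresholdFit
    modules: net.ModuleSet
    eigengenes: pd.DataFrame
    arm_a: list[assoc.RegressionResult]
    arm_a_bh: pd.DataFrame
    arm_b: list[assoc.RegressionResult]
    arm_c: list[assoc.RegressionResult]
    candidates: list[tuple[str, str]]
    mediation_report: pd.DataFrame
    mediation_results: list[med.MediationResult]
    enrichment: pd.DataFrame = field(default_factory=pd.DataFrame)
    probe_pvalues: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_pipeline(
    config: syn.CohortConfig,
    frac_correlated: float = 0.8,
    n_variable_probes: int = 300,
    n_cell_types: int = 5,
    soft_powers=(4, 5, 6),
    min_module_size: int = 10,
    alpha: float = 0.05,
    fdr: float = 0.10,
    n_boot: int = 2000,
    run_enrichment: bool = True,
    gene_set_size_range: tuple[int, int] = (20, 200),
    deconv_restarts: int = 4,
) -> PipelineResult:
    """Simulate one cohort and run the full analysis on it.

    Network-stage sizes (probe counts, bootstrap draws, gene-set sizes) are
    arguments so callers can scale the run; the statistical thresholds
    default to the gating alpha of 0.05 and FDR of 0.10 used throughout.
    """
    phenos, latents = syn.generate_cohort(config)
    beta, manifest, labels = syn.generate_methylation(phenos, config, latents)

    # --- preprocessing: quantile-normalize betas, drop design-flagged
    # probes, then keep only cross-tissue-correlated loci (M scale onwards)
    beta_qn = prep.quantile_normalize(beta)
    m = prep.beta_to_m(beta_qn)
    m_filt, _report = prep.filter_probes(m, manifest, drop_crosshyb=True)
    reference, _truth_flags = syn.generate_brain_saliva_reference(
        beta_qn.loc[:, m_filt.columns], frac_correlated=frac_correlated,
        seed=int(np.random.default_rng([config.seed, 11]).integers(2**31)))
    retained, _stats = prep.brain_saliva_filter(
        beta_qn.loc[:, m_filt.columns], reference, alpha=alpha)
    m_kept = m_filt.loc[:, retained]

    # --- cellular heterogeneity covariates
    top = deconv.select_variable_probes(beta_qn, min(n_variable_probes, beta_qn.shape[1]))
    mixture = deconv.estimate_cell_mixture(
        beta_qn.loc[:, top], k=n_cell_types,
        seed=int(np.random.default_rng([config.seed, 12]).integers(2**31)),
        n_restarts=deconv_restarts)
    # drop the last proportion column: simplex rows are collinear with the
    # intercept if all K enter the design
    cell_covs = mixture.proportions.iloc[:, :-1]

    # --- co-methylation network on residualized M-values
    covariates = pd.concat(
        [phenos[["age", "sex", "mds1", "mds2", "mds3", "mds4"]], cell_covs], axis=1)
    resid = net.residualize(m_kept, covariates)
    sft = net.pick_soft_threshold(resid, candidate_powers=soft_powers)
    network = net.build_network(resid, sft.power)
    modules = net.detect_modules(network, min_size=min_module_size)
    eigengenes = net.module_eigengenes(resid, modules)

    # --- Arm A: FEH -> volumes, BH over all non-intercept terms
    arm_a = [assoc.fit_arm_a(phenos, r) for r in syn.REGIONS]
    all_ps = [row["p"] for res in arm_a
              for term, row in res.terms.iterrows() if term != "const"]
    arm_a_bh = assoc.bh_adjust(all_ps, fdr=fdr, m_tests=assoc.family_size(arm_a))
    regions_passing = [r.outcome for r in assoc.gate(arm_a, alpha)]

    # --- Arm B: FEH -> eigengenes
    arm_b = [assoc.fit_arm_b(eigengenes[c], phenos) for c in eigengenes.columns]
    mes_passing_b = [r.outcome for r in assoc.gate(arm_b, alpha)]

    # --- Arm C: surviving eigengenes -> surviving volumes
    arm_c = []
    for me_name in mes_passing_b:
        for region in regions_passing:
            arm_c.append(assoc.fit_arm_c(phenos, eigengenes[me_name], region))
    candidates = [(r.predictor, r.outcome) for r in assoc.gate(arm_c, alpha)]

    # --- mediation of surviving (ME, region) pairs
    mediation_report, mediation_results = med.mediation_screen(
        phenos, eigengenes, candidates, n_boot=n_boot,
        seed=int(np.random.default_rng([config.seed, 13]).integers(2**31)), fdr=fdr)

    enrichment_res = pd.DataFrame()
    probe_ps = pd.DataFrame()
    if run_enrichment:
        probe_ps = enrich.probe_association(resid, phenos)
        scores = enrich.gene_scores(probe_ps["p"], manifest)
        planted = syn.mediator_genes(manifest, labels,
                                     module=config.mediator_module_ids[0] + 1)
        sets = syn.generate_gene_sets(
            manifest, n_sets=25, size_range=gene_set_size_range,
            seed=int(np.random.default_rng([config.seed, 14]).integers(2**31)),
            planted_genes=planted)
        enrichment_res = enrich.test_gene_sets(
            scores, sets, min_size=gene_set_size_range[0],
            max_size=gene_set_size_range[1], fdr=fdr)
        enrichment_res = enrich.reduce_redundancy(enrichment_res, sets, jaccard_max=0.5)

    return PipelineResult(
        config=config, phenos=phenos, latents=latents, beta=beta,
        manifest=manifest, true_labels=labels, retained_probes=retained,
        mixture=mixture, resid=resid, soft_threshold=sft, modules=modules,
        eigengenes=eigengenes, arm_a=arm_a, arm_a_bh=arm_a_bh, arm_b=arm_b,
        arm_c=arm_c, candidates=candidates,
        mediation_report=mediation_report, mediation_results=mediation_results,
        enrichment=enrichment_res, probe_pvalues=probe_ps,
    )
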