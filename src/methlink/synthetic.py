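"""Seeded synthetic cohorts with planted co-methylation structure.

The generator emulates the study design this package analyzes: ~100 young
adults with a 70-item family-emotional-health (FEH) questionnaire score, a
past-year stressful-life-events (SLE) impact score negatively correlated
with FEH, four genomic-ancestry components, FreeSurfer-style fronto-limbic
region volumes, and a saliva MethylationEPIC-style beta matrix containing
planted correlated probe modules. Selected modules are *mediators*: their
latent factor is driven by FEH (slope ``a_effect``) and in turn drives a
target region volume (slope ``b_effect``), alongside a direct FEH effect
(``c_direct``), so the downstream association and mediation machinery has a
known ground truth to recover.

Everything is reproducible from ``CohortConfig.seed``; planted truth
(module labels, effect sizes, cross-tissue flags) is returned alongside the
data so recovery tests never have to re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocess import m_to_beta

REGIONS = (
    "left_hippocampus", "right_hippocampus",
    "left_dlpfc", "right_dlpfc",
    "left_mpfc", "right_mpfc",
    "left_amygdala", "right_amygdala",
)

# Cohort-scale region means and SDs (mm^3), overridable via CohortConfig.
REGION_STATS: dict[str, tuple[float, float]] = {
    "left_hippocampus": (4650.0, 446.0),
    "right_hippocampus": (4741.0, 392.0),
    "left_dlpfc": (11980.0, 1785.0),
    "right_dlpfc": (10639.0, 1585.0),
    "left_mpfc": (5745.0, 853.0),
    "right_mpfc": (5790.0, 717.0),
    "left_amygdala": (1655.0, 186.0),
    "right_amygdala": (1859.0, 210.0),
}
TBV_MEAN, TBV_SD = 1.2e6, 1.2e5

# One-factor probit item model for the 70-item FEH questionnaire:
# P(item = "no" | z) = Phi(ITEM_TAU + ITEM_LOADING * z), z ~ N(0,1) with the
# liability floored at ITEM_Z_FLOOR so scores respect the questionnaire's
# observed floor (cohort range 34-70) instead of drifting arbitrarily low.
# Calibrated so the score has mean ~60 and SD ~8.6 on the 0-70 scale.
ITEM_TAU = 1.2
ITEM_LOADING = 0.55
ITEM_Z_FLOOR = -2.5
# corr(FEH score, latent z) under the item model above; used to convert the
# requested FEH-SLE correlation into a loading on the shared latent.
_FEH_LATENT_CORR = 0.89

FEH_ITEMS = 70
SLE_ITEMS = 45
SLE_MEAN, SLE_SD = 11.0, 7.6


@dataclass
class CohortConfig:
    """All knobs of the synthetic study, with cohort-scale defaults.

    Effect-size defaults are chosen so one planted mediator module carries a
    right-amygdala mediation of realistic magnitude: total FEH slope
    ``c_direct + a_effect*b_effect`` ~ 5.7 mm^3 per FEH unit, of which
    ~1.3 mm^3 flows through the module latent.
    """

    n_subjects: int = 98
    n_probes: int = 2000
    n_modules: int = 10
    module_size: int = 20
    mediator_module_ids: tuple[int, ...] = (0,)
    target_region: str = "right_amygdala"
    a_effect: float = 0.03       # module-latent units per FEH unit
    b_effect: float = 44.0       # mm^3 per module-latent unit
    c_direct: float = 4.33       # mm^3 per FEH unit, direct path
    feh_sle_corr: float = -0.44
    latent_noise_sd: float = 1.0  # SD of module latent around its FEH part
    probe_noise_sd: float = 0.6   # per-probe noise on the M scale
    volume_noise_frac: float = 0.8  # residual volume SD as fraction of region SD
    tbv_corr: float = 0.6         # target corr(region volume, TBV)
    female_frac: float = 0.69
    n_genes: int = 1200
    # cell heterogeneity: K=5 saliva-like mixture whose marker probes carry
    # large M-scale cell-type contrasts and dominate the variance ranking,
    # as composition does on real arrays
    n_cell_markers: int = 300
    cell_marker_coef_sd: float = 4.0
    cell_alpha: tuple[float, ...] = (4.0, 2.0, 1.0, 0.75, 0.25)
    region_stats: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(REGION_STATS))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_probes", "n_modules", "module_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.module_size < 2:
            raise ValueError("module_size must be >= 2")
        if self.n_modules * self.module_size > self.n_probes:
            raise ValueError("planted modules exceed probe count")
        if self.n_modules * self.module_size + self.n_cell_markers > self.n_probes:
            raise ValueError("planted modules plus cell markers exceed probe count")
        if not abs(self.feh_sle_corr) < 1:
            raise ValueError("|feh_sle_corr| must be < 1")
        if abs(self.feh_sle_corr) >= _FEH_LATENT_CORR:
            raise ValueError(
                f"|feh_sle_corr| >= {_FEH_LATENT_CORR} is infeasible under the "
                "item model (FEH itself is an imperfect measure of its latent)")
        bad = [m for m in self.mediator_module_ids if not 0 <= m < self.n_modules]
        if bad:
            raise ValueError(f"mediator module ids out of range: {bad}")
        if self.target_region not in self.region_stats:
            raise ValueError(f"unknown target region {self.target_region!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    # independent, reproducible sub-streams per pipeline stage
    return np.random.default_rng([config.seed, stream])


def score_feh(item_responses) -> int:
    """Score the 70-item family-history questionnaire.

    Each "no" contributes one point, so higher scores mean healthier family
    emotional history; the score spans [0, 70].
    """
    items = list(item_responses)
    if len(items) != FEH_ITEMS:
        raise ValueError(f"expected {FEH_ITEMS} items, got {len(items)}")
    bad = {it for it in items if it not in ("yes", "no")}
    if bad:
        raise ValueError(f"non-binary responses: {sorted(bad)}")
    return sum(1 for it in items if it == "no")


def _draw_feh(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Item-level FEH draws; returns (scores, latent z)."""
    z = np.maximum(rng.standard_normal(n), ITEM_Z_FLOOR)
    p_no = norm.cdf(ITEM_TAU + ITEM_LOADING * z)
    items = rng.random((n, FEH_ITEMS)) < p_no[:, None]
    return items.sum(axis=1).astype(int), z


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the phenotype table and the planted module latent scores.

    Returns ``(phenotypes, latents)`` where ``latents`` is an
    n_subjects x n_modules frame of the per-module latent factors that the
    methylation probes will load on. Mediator-module latents contain
    ``a_effect * (FEH - mean)``; the target-region volume adds
    ``b_effect * latent`` for each mediator plus the direct FEH term.
    """
    if config.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    rng = _rng(config, 1)
    n = config.n_subjects

    feh, z = _draw_feh(rng, n)

    # SLE shares the FEH latent; loading rescaled by the item-model
    # attenuation so the *score* correlation hits the requested target.
    rho = config.feh_sle_corr / _FEH_LATENT_CORR
    sle_lat = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    sle = np.maximum(np.rint(SLE_MEAN + SLE_SD * sle_lat), 0.0)
    sle = np.minimum(sle, float(SLE_ITEMS))

    age = rng.uniform(18.0, 22.0, n)
    sex = (rng.random(n) < config.female_frac).astype(int)  # female = 1
    mds = rng.normal(0.0, 0.05, (n, 4))

    latents = _module_latents(config, feh)

    tbv = rng.normal(TBV_MEAN, TBV_SD, n)
    feh_c = feh - feh.mean()
    vols = {}
    for region in REGIONS:
        mean_r, sd_r = config.region_stats[region]
        beta_tbv = config.tbv_corr * sd_r / TBV_SD
        v = (mean_r
             + beta_tbv * (tbv - TBV_MEAN)
             + rng.normal(0.0, config.volume_noise_frac * sd_r, n))
        if region == config.target_region:
            v = v + config.c_direct * feh_c
            for m in config.mediator_module_ids:
                v = v + config.b_effect * latents[:, m]
        vols[region] = np.maximum(v, 1.0)

    phenos = pd.DataFrame({
        "age": age, "sex": sex, "feh": feh, "sle": sle,
        "mds1": mds[:, 0], "mds2": mds[:, 1],
        "mds3": mds[:, 2], "mds4": mds[:, 3],
        **vols,
        "tbv": tbv,
    }, index=pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id"))
    lat = pd.DataFrame(latents, index=phenos.index,
                       columns=[f"module_{m}" for m in range(config.n_modules)])
    return phenos, lat


def _module_latents(config: CohortConfig, feh: np.ndarray) -> np.ndarray:
    """Per-module latent factors, FEH-driven for mediator modules.

    Seeded independently of the cohort stream so that
    :func:`generate_methylation` can re-derive the identical latents from
    the phenotype table alone.
    """
    rng = _rng(config, 2)
    n = len(feh)
    latents = rng.normal(0.0, config.latent_noise_sd, (n, config.n_modules))
    feh_c = feh - feh.mean()
    for m in config.mediator_module_ids:
        latents[:, m] += config.a_effect * feh_c
    return latents


def true_cell_proportions(config: CohortConfig, n: int) -> np.ndarray:
    """The planted Dirichlet cell-type proportions (own seed stream, so the
    deconvolution truth is recoverable without regenerating the matrix)."""
    rng = _rng(config, 4)
    return rng.dirichlet(config.cell_alpha, n)


def generate_methylation(
    phenos: pd.DataFrame,
    config: CohortConfig,
    latents: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Beta matrix, probe manifest and true module labels.

    Module probes load on their module's latent with unit-scale loadings of
    random sign; small age, sex and cell-proportion effects are added on the
    M scale before the inverse-logit back to beta. The manifest deliberately
    plants X/Y-chromosome, rs and cross-hybridizing probes (background
    probes only) so the preprocessing filters have something to remove.

    Returns ``(beta, manifest, labels)`` with ``labels`` mapping probe id to
    planted module (1-based; 0 = background).
    """
    n, p = len(phenos), config.n_probes
    n_planted = config.n_modules * config.module_size
    if n_planted > p:
        raise ValueError("planted modules exceed probe count")
    if latents is None:
        lat = _module_latents(config, phenos["feh"].to_numpy())
    else:
        lat = latents.to_numpy()
    rng = _rng(config, 3)

    labels = np.zeros(p, dtype=int)
    for m in range(config.n_modules):
        labels[m * config.module_size:(m + 1) * config.module_size] = m + 1

    mu = rng.normal(0.0, 2.0, p)
    loadings = rng.uniform(0.8, 1.2, p) * rng.choice([-1.0, 1.0], p)
    age_coef = rng.normal(0.0, 0.02, p)
    sex_coef = rng.normal(0.0, 0.1, p)
    cell_props = true_cell_proportions(config, n)
    k_cells = cell_props.shape[1]
    cell_coef = rng.normal(0.0, 0.3, (k_cells, p))
    # marker probes (the last n_cell_markers, all background) carry large
    # cell-type contrasts so composition dominates the variance ranking
    markers = slice(p - config.n_cell_markers, p)
    cell_coef[:, markers] = rng.normal(0.0, config.cell_marker_coef_sd,
                                       (k_cells, config.n_cell_markers))

    M = np.tile(mu, (n, 1))
    for m in range(config.n_modules):
        cols = slice(m * config.module_size, (m + 1) * config.module_size)
        M[:, cols] += np.outer(lat[:, m], loadings[cols])
    age = phenos["age"].to_numpy()
    sex = phenos["sex"].to_numpy()
    M += np.outer(age - age.mean(), age_coef)
    M += np.outer(sex, sex_coef)
    M += (cell_props - cell_props.mean(axis=0)) @ cell_coef
    M += rng.normal(0.0, config.probe_noise_sd, (n, p))

    beta = m_to_beta(M)

    manifest, probe_ids = _build_manifest(config, labels, rng)
    beta_df = pd.DataFrame(beta, index=phenos.index, columns=probe_ids)
    label_s = pd.Series(labels, index=probe_ids, name="module")
    return beta_df, manifest, label_s


def _build_manifest(config: CohortConfig, labels: np.ndarray,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, pd.Index]:
    p = config.n_probes
    background = labels == 0
    n_bg = int(background.sum())

    # flag fractions of the background: sex chromosomes, rs, cross-hyb
    flags = np.array(["clean"] * p, dtype=object)
    bg_idx = np.flatnonzero(background)
    rng.shuffle(bg_idx)
    cuts = np.cumsum([int(0.02 * n_bg), int(0.01 * n_bg),
                      int(0.01 * n_bg), int(0.02 * n_bg)])
    flags[bg_idx[:cuts[0]]] = "X"
    flags[bg_idx[cuts[0]:cuts[1]]] = "Y"
    flags[bg_idx[cuts[1]:cuts[2]]] = "rs"
    flags[bg_idx[cuts[2]:cuts[3]]] = "crosshyb"

    chrom = rng.integers(1, 23, p).astype(object)
    chrom[flags == "X"] = "X"
    chrom[flags == "Y"] = "Y"
    position = rng.integers(1, 2_000_000, p)

    probe_ids = np.array([f"cg{i:07d}" for i in range(p)], dtype=object)
    probe_ids[flags == "rs"] = [f"rs{i:06d}" for i in np.flatnonzero(flags == "rs")]

    # gene annotation: ~90% of probes carry 1-2 symbols from a finite universe
    genes = np.array([f"GENE{i:05d}" for i in range(config.n_genes)], dtype=object)
    gene_symbols = []
    for i in range(p):
        k = rng.choice([0, 1, 2], p=[0.1, 0.75, 0.15])
        gene_symbols.append(";".join(rng.choice(genes, size=k, replace=False)))

    manifest = pd.DataFrame({
        "chromosome": [str(c) for c in chrom],
        "position": position,
        "gene_symbols": gene_symbols,
        "is_rs_probe": flags == "rs",
        "is_crosshyb": flags == "crosshyb",
    }, index=pd.Index(probe_ids, name="probe_id"))
    return manifest, pd.Index(probe_ids, name="probe_id")


def mediator_genes(manifest: pd.DataFrame, labels: pd.Series,
                   module: int = 1) -> list[str]:
    """Gene symbols carried by the probes of a planted module."""
    probes = labels.index[labels == module]
    out: list[str] = []
    for s in manifest.loc[probes, "gene_symbols"]:
        for g in str(s).split(";"):
            if g and g not in out:
                out.append(g)
    return out


def generate_brain_saliva_reference(
    beta: pd.DataFrame,
    frac_correlated: float,
    seed: int,
    noise_sd: float = 0.5,
    n_pairs: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Paired cross-tissue reference matrix emulating a brain/saliva resource.

    For a random ``frac_correlated`` of probes the reference column is the
    saliva column plus M-scale noise (a genuinely cross-tissue-correlated
    locus); the rest are row-permuted so their pairing carries no signal.
    Returns the reference beta matrix and a boolean truth series flagging
    the correlated probes.
    """
    if not 0.0 <= frac_correlated <= 1.0:
        raise ValueError("frac_correlated must be in [0, 1]")
    if beta.size == 0:
        raise ValueError("empty beta matrix")
    rng = np.random.default_rng(seed)
    sub = beta if n_pairs is None else beta.iloc[:n_pairs]
    n, p = sub.shape
    from .preprocess import beta_to_m
    M = beta_to_m(sub).to_numpy()
    n_corr = int(round(frac_correlated * p))
    flagged = np.zeros(p, dtype=bool)
    flagged[rng.choice(p, size=n_corr, replace=False)] = True

    ref = np.empty_like(M)
    ref[:, flagged] = M[:, flagged] + rng.normal(0.0, noise_sd, (n, int(flagged.sum())))
    for j in np.flatnonzero(~flagged):
        ref[:, j] = rng.permutation(M[:, j])
    ref_beta = m_to_beta(ref)
    ref_df = pd.DataFrame(ref_beta, index=sub.index, columns=sub.columns)
    truth = pd.Series(flagged, index=sub.columns, name="is_cross_tissue")
    return ref_df, truth


def generate_gene_sets(
    manifest: pd.DataFrame,
    n_sets: int = 30,
    size_range: tuple[int, int] = (50, 1000),
    seed: int = 0,
    planted_genes: list[str] | None = None,
) -> dict[str, list[str]]:
    """Random gene sets over the manifest's gene universe, plus decoys.

    Two deliberately out-of-range decoy sets (one below the size floor, one
    above the ceiling, universe permitting) exercise the size filter. If
    ``planted_genes`` is given, a set named ``SET_PLANTED`` containing them
    (topped up with random genes to the floor size) is included.
    """
    universe: list[str] = []
    for s in manifest["gene_symbols"]:
        for g in str(s).split(";"):
            if g and g not in universe:
                universe.append(g)
    if not universe:
        raise ValueError("manifest has an empty gene universe")
    rng = np.random.default_rng(seed)
    uni = np.array(universe, dtype=object)
    lo, hi = size_range
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, min(hi, len(uni)) + 1))
        sets[f"SET_{i:03d}"] = list(rng.choice(uni, size=size, replace=False))
    if lo > 1:
        sets["SET_DECOY_SMALL"] = list(rng.choice(uni, size=lo - 1, replace=False))
    if hi + 1 <= len(uni):
        sets["SET_DECOY_LARGE"] = list(rng.choice(uni, size=hi + 1, replace=False))
    if planted_genes:
        extra = [g for g in uni if g not in planted_genes]
        # pad past the floor so universe intersection downstream cannot
        # push the set below the size window
        target = lo + max(5, lo // 4)
        top_up = max(0, target - len(planted_genes))
        chosen = list(planted_genes) + list(rng.choice(extra, size=top_up, replace=False))
        sets["SET_PLANTED"] = chosen
    return sets


def generate_mixture_betas(
    n_samples: int,
    n_probes: int,
    k: int,
    noise_sd: float = 0.02,
    seed: int = 0,
    alpha: tuple[float, ...] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Linear cell-type mixture on the beta scale, for deconvolution tests.

    ``beta = P @ F.T + noise`` with Dirichlet proportions ``P`` (rows on the
    simplex) and uniform profiles ``F`` in [0, 1]; the observed matrix is
    clipped to (0, 1). Returns ``(beta, P, F)`` with the planted truth.
    """
    rng = np.random.default_rng(seed)
    if alpha is None:
        alpha = tuple(np.linspace(8.0, 1.0, k))
    P = rng.dirichlet(alpha, n_samples)
    F = rng.uniform(0.0, 1.0, (n_probes, k))
    Y = P @ F.T + rng.normal(0.0, noise_sd, (n_samples, n_probes))
    Y = np.clip(Y, 1e-4, 1 - 1e-4)
    beta = pd.DataFrame(
        Y,
        index=[f"S{i:04d}" for i in range(n_samples)],
        columns=[f"cg{j:07d}" for j in range(n_probes)],
    )
    return beta, P, F
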