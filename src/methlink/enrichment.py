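"""Methylome-wide FEH association and probe-count-aware gene-set enrichment.

Each residualized probe M-value is tested as a predictor of FEH (SLE
adjusted) under a weakly-informative zero-mean normal prior on slopes; a
flat-prior mode reproduces the classical OLS t-test exactly and serves as
the frequentist cross-check. Probe p-values aggregate to genes by a
Sidak-corrected minimum (penalizing genes that simply carry more probes),
and gene sets within a size window are tested by a one-sided rank-sum
comparison of in-set versus out-of-set gene scores. A greedy Jaccard sweep
condenses the ranked results to non-redundant sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust


def probe_association(
    resid: pd.DataFrame,
    phenos: pd.DataFrame,
    extra_covariates: list[str] | None = None,
    prior_sd: float | None = 10.0,
) -> pd.DataFrame:
    """Per-probe regression of FEH on the probe's residual M-value.

    Covariates are SLE plus any ``extra_covariates`` columns of ``phenos``.
    With ``prior_sd`` set, slope coefficients get independent N(0,
    prior_sd^2) priors (intercept flat) and the two-sided p comes from the
    normal posterior tail with a plug-in residual variance; with
    ``prior_sd=None`` the fit is maximum likelihood and the p is the exact
    OLS t-test.

    Returns a per-probe table with columns ``b``, ``se`` and ``p``.
    """
    phenos = phenos.loc[resid.index]
    y = phenos["feh"].to_numpy(dtype=float)
    covs = ["sle", *(extra_covariates or [])]
    C = phenos[covs].to_numpy(dtype=float)
    n = len(y)
    out = np.empty((resid.shape[1], 3))
    for j, probe in enumerate(resid.columns):
        x = resid[probe].to_numpy(dtype=float)
        if x.std() == 0:
            raise ValueError(f"constant probe {probe!r}")
        X = np.column_stack([np.ones(n), x, C])
        k = X.shape[1]
        XtX = X.T @ X
        Xty = X.T @ y
        beta_ols = np.linalg.solve(XtX, Xty)
        resid_y = y - X @ beta_ols
        sigma2 = float(resid_y @ resid_y) / (n - k)
        if prior_sd is None:
            cov = sigma2 * np.linalg.inv(XtX)
            b, se = beta_ols[1], np.sqrt(cov[1, 1])
            p = 2.0 * stats.t.sf(abs(b / se), n - k)
        else:
            prec = XtX / sigma2
            prior_prec = np.zeros(k)
            prior_prec[1:] = 1.0 / prior_sd**2   # flat on the intercept
            post_cov = np.linalg.inv(prec + np.diag(prior_prec))
            post_mean = post_cov @ (Xty / sigma2)
            b, se = post_mean[1], np.sqrt(post_cov[1, 1])
            p = 2.0 * stats.norm.sf(abs(b / se))
        out[j] = (b, se, p)
    return pd.DataFrame(out, index=resid.columns, columns=["b", "se", "p"])


def gene_scores(probe_ps: pd.Series, manifest: pd.DataFrame) -> pd.DataFrame:
    """Aggregate probe p-values to genes with a Sidak minimum-p adjustment.

    For a gene with n mapped probes and best probe p, the adjusted gene
    score is ``1 - (1 - min_p)^n``, which penalizes probe-rich genes that
    would otherwise win on the minimum alone. Probes mapped to several
    genes contribute to each; unannotated probes are dropped here (and only
    here). Genes with zero scored probes are excluded.
    """
    mapping: dict[str, list[float]] = {}
    annot = manifest.loc[probe_ps.index, "gene_symbols"]
    for probe, genes in annot.items():
        p = probe_ps[probe]
        for g in str(genes).split(";"):
            if g and g != "nan":
                mapping.setdefault(g, []).append(float(p))
    rows = []
    for gene, ps in mapping.items():
        min_p = min(ps)
        adj = 1.0 - (1.0 - min_p) ** len(ps)
        rows.append({"gene": gene, "n_probes": len(ps),
                     "min_p": min_p, "adjusted_p": adj})
    df = pd.DataFrame(rows).set_index("gene")
    return df.sort_index()


def test_gene_sets(
    scores: pd.DataFrame,
    sets: dict[str, list[str]],
    min_size: int = 50,
    max_size: int = 1000,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Rank-sum enrichment of each size-eligible gene set.

    Sets are intersected with the scored universe first; only those with
    between ``min_size`` and ``max_size`` surviving genes are tested, which
    drops both sparse sets and high-level catch-all terms. The test asks,
    one-sided, whether in-set genes have larger ``-log(adjusted_p)`` than
    the rest of the universe. Results carry BH flags (across tested sets)
    and are ranked by p.
    """
    if scores.empty:
        raise ValueError("empty gene-score universe")
    universe = set(scores.index)
    stat = -np.log(np.maximum(scores["adjusted_p"].to_numpy(), 1e-300))
    stat = pd.Series(stat, index=scores.index)
    rows = []
    for name, genes in sets.items():
        members = sorted(universe.intersection(genes))
        if not min_size <= len(members) <= max_size:
            continue
        in_set = stat.loc[members].to_numpy()
        out_set = stat.drop(index=members).to_numpy()
        if len(out_set) == 0:
            raise ValueError(f"set {name!r} covers the whole universe")
        res = stats.mannwhitneyu(in_set, out_set, alternative="greater")
        rows.append({"set": name, "size": len(members), "p": float(res.pvalue)})
    result = pd.DataFrame(rows, columns=["set", "size", "p"])
    if len(result):
        bh = bh_adjust(result["p"], fdr=fdr)
        result["bh_significant"] = bh["significant"].to_numpy()
        result = result.sort_values("p", kind="stable").reset_index(drop=True)
        result["rank"] = np.arange(1, len(result) + 1)
    else:
        result["bh_significant"] = pd.Series(dtype=bool)
        result["rank"] = pd.Series(dtype=int)
    return result


def reduce_redundancy(
    results: pd.DataFrame,
    sets: dict[str, list[str]],
    jaccard_max: float = 0.5,
) -> pd.DataFrame:
    """Greedy non-redundant summary of ranked enrichment results.

    Sweeping by ascending p, a set is dropped when its Jaccard gene overlap
    with any already-retained set exceeds ``jaccard_max``; with
    ``jaccard_max = 1`` everything survives.
    """
    kept_rows = []
    kept_genes: list[set[str]] = []
    for _, row in results.sort_values("p", kind="stable").iterrows():
        genes = set(sets[row["set"]])
        redundant = False
        for prev in kept_genes:
            inter = len(genes & prev)
            union = len(genes | prev)
            if union and inter / union > jaccard_max:
                redundant = True
                break
        if not redundant:
            kept_rows.append(row)
            kept_genes.append(genes)
    return pd.DataFrame(kept_rows).reset_index(drop=True)
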