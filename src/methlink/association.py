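"""Gated association analyses linking FEH, module eigengenes and brain
region volumes, with Benjamini-Hochberg FDR control.

Three regression arms are run in sequence, each gated at p < 0.05:

* **Arm A** — FEH predicts each hemisphere-specific region volume,
  adjusting for age, sex, four ancestry components, past-year SLEs and
  total brain volume (TBV).
* **Arm B** — FEH predicts each module eigengene, adjusting for SLEs only
  (age/sex/ancestry/cell effects were already removed by residualization).
* **Arm C** — each surviving eigengene predicts the surviving volumes with
  Arm A's covariates.

All models use unstandardized continuous predictors, so coefficients are in
outcome units per predictor unit (mm^3 per FEH point, etc.). Every arm can
be re-run without the TBV covariate as a sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .preprocess import pearson_pvalues

ARM_A_COVARIATES = ("age", "sex", "mds1", "mds2", "mds3", "mds4", "sle", "tbv")


@dataclass
class RegressionResult:
    """One fitted OLS model: term table plus fit summaries."""

    outcome: str
    predictor: str                 # the focal term (FEH or an ME)
    terms: pd.DataFrame            # index = term; columns b, se, t, p
    adj_r2: float
    rse: float                     # residual standard error
    n: int

    @property
    def focal(self) -> pd.Series:
        return self.terms.loc[self.predictor]

    @property
    def n_terms(self) -> int:
        """Non-intercept coefficient count (the BH-family contribution)."""
        return int((self.terms.index != "const").sum())


def _fit_ols(y: pd.Series, X: pd.DataFrame, outcome: str,
             predictor: str) -> RegressionResult:
    data = pd.concat([y, X], axis=1).dropna()
    yv = data.iloc[:, 0]
    Xv = sm.add_constant(data.iloc[:, 1:], has_constant="add")
    if np.linalg.matrix_rank(Xv.to_numpy()) < Xv.shape[1]:
        raise np.linalg.LinAlgError(f"collinear design for outcome {outcome!r}")
    if yv.std() == 0:
        raise ValueError(f"constant outcome {outcome!r}")
    fit = sm.OLS(yv, Xv).fit()
    terms = pd.DataFrame({
        "b": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
    })
    return RegressionResult(
        outcome=outcome, predictor=predictor, terms=terms,
        adj_r2=float(fit.rsquared_adj),
        rse=float(np.sqrt(fit.mse_resid)),
        n=int(fit.nobs),
    )


def fit_arm_a(phenos: pd.DataFrame, region: str,
              include_tbv: bool = True) -> RegressionResult:
    """FEH -> region volume with the full covariate set."""
    covs = [c for c in ARM_A_COVARIATES if include_tbv or c != "tbv"]
    X = phenos[["feh", *covs]]
    return _fit_ols(phenos[region], X, outcome=region, predictor="feh")


def fit_arm_b(me: pd.Series, phenos: pd.DataFrame) -> RegressionResult:
    """FEH -> module eigengene, SLE-adjusted."""
    if me.std() == 0:
        raise ValueError("constant module eigengene")
    X = phenos.loc[me.index, ["feh", "sle"]]
    return _fit_ols(me, X, outcome=str(me.name), predictor="feh")


def fit_arm_c(phenos: pd.DataFrame, me: pd.Series, region: str,
              include_tbv: bool = True) -> RegressionResult:
    """Module eigengene -> region volume with Arm A's covariates."""
    covs = [c for c in ARM_A_COVARIATES if include_tbv or c != "tbv"]
    me = me.rename(me.name or "me")
    X = pd.concat([me, phenos.loc[me.index, list(covs)]], axis=1)
    return _fit_ols(phenos.loc[me.index, region], X,
                    outcome=region, predictor=str(me.name))


def arm_table(results: list[RegressionResult]) -> pd.DataFrame:
    """Stack fitted models into a long per-term report table."""
    rows = []
    for res in results:
        for term, row in res.terms.iterrows():
            rows.append({
                "outcome": res.outcome, "predictor": res.predictor,
                "term": term, "b": row["b"], "se": row["se"],
                "t": row["t"], "p": row["p"],
                "adj_r2": res.adj_r2, "rse": res.rse, "n": res.n,
            })
    return pd.DataFrame(rows)


def family_size(results: list[RegressionResult]) -> int:
    """BH family size: every non-intercept coefficient across the models."""
    return sum(res.n_terms for res in results)


def bh_adjust(pvals, fdr: float = 0.10, m_tests: int | None = None) -> pd.DataFrame:
    """Benjamini-Hochberg step-up over a declared family of tests.

    Each p-value's critical value is ``rank / m * fdr``; all tests up to the
    largest rank whose p-value sits below its critical value are flagged.
    ``m_tests`` may exceed ``len(pvals)`` to correct within a declared
    family larger than the p-values supplied.
    """
    p = np.asarray(list(pvals), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    m = len(p) if m_tests is None else int(m_tests)
    if m < len(p):
        raise ValueError("m_tests smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranks = np.empty(len(p), dtype=int)
    ranks[order] = np.arange(1, len(p) + 1)
    crit = ranks / m * fdr
    below = p <= crit
    if below.any():
        threshold = p[below].max()
        flag = p <= threshold
    else:
        flag = np.zeros(len(p), dtype=bool)
    return pd.DataFrame({
        "p": p, "rank": ranks, "critical": crit, "significant": flag,
    })


def gate(results: list[RegressionResult], alpha: float = 0.05) -> list[RegressionResult]:
    """Graduate models whose focal term reaches p < alpha, in input order."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return [res for res in results if res.focal["p"] < alpha]


def correlation_heatmap(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over the table's columns."""
    if table.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    X = table.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        const = table.columns[X.std(axis=0) == 0]
        raise ValueError(f"constant variables: {list(const)}")
    cols = table.columns
    k = len(cols)
    R = np.eye(k)
    P = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = pearson_pvalues(X[:, [i]], X[:, [j]])
            R[i, j] = R[j, i] = r[0]
            P[i, j] = P[j, i] = p[0]
    return (pd.DataFrame(R, index=cols, columns=cols),
            pd.DataFrame(P, index=cols, columns=cols))


def plot_correlation_heatmap(r: pd.DataFrame, path) -> None:
    """Save the correlation matrix as a diverging heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.5 * len(r) + 2, 0.5 * len(r) + 2))
    im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(r)), r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(r)), r.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def paired_t(left, right) -> dict:
    """Two-sided paired t-test of hemispheric volume differences."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(left)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = left - right
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return {"t": 0.0, "p": 1.0, "mean_left": float(left.mean()),
                    "mean_right": float(right.mean()), "n": n}
        raise ValueError("zero-variance nonzero difference")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return {"t": float(t), "p": float(p), "mean_left": float(left.mean()),
            "mean_right": float(right.mean()), "n": n}
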