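"""Bootstrap mediation of the FEH -> brain-volume effect through module
eigengenes (and, for fully mediating modules, through individual probes).

The decomposition is the linear product-of-coefficients one, with no
treatment-mediator interaction:

* mediator model:  ``ME ~ FEH + SLE``
* outcome model:   ``volume ~ FEH + ME + age + sex + ancestry + SLE (+ TBV)``

For an exposure contrast ``delta = treat - control`` on the FEH scale, the
indirect effect is ``IDE = a * b * delta`` (a = FEH slope on the mediator,
b = mediator slope on the outcome), the direct effect ``DE = c' * delta``,
and ``TE = IDE + DE`` exactly, in every bootstrap draw. Uncertainty comes
from a nonparametric case-resampling bootstrap (subjects resampled with
replacement, both models refit per draw) with percentile intervals and a
two-sided bootstrap p with a ``1/(B+1)`` continuity floor.

The default contrast spans the observed FEH range from its minimum (poorest
family emotional health) to its maximum, so effects read as the expected
volume difference between the worst- and best-scoring subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import ARM_A_COVARIATES, bh_adjust

EFFECTS = ("IDE", "DE", "TE")


@dataclass
class EffectEstimate:
    estimate: float
    ci_lower: float
    ci_upper: float
    p: float

    @property
    def nonzero(self) -> bool:
        """Effect distinguishable from zero: its 95% CI excludes 0."""
        return not (self.ci_lower <= 0.0 <= self.ci_upper)


@dataclass
class MediationResult:
    mediator: str
    outcome: str
    effects: dict[str, EffectEstimate]
    treat_value: float
    control_value: float
    n_boot: int
    seed: int
    n_redrawn: int = 0
    draws: dict[str, np.ndarray] | None = field(default=None, repr=False)

    @property
    def ide(self) -> EffectEstimate:
        return self.effects["IDE"]

    @property
    def de(self) -> EffectEstimate:
        return self.effects["DE"]

    @property
    def te(self) -> EffectEstimate:
        return self.effects["TE"]


def _designs(phenos: pd.DataFrame, mediator: np.ndarray, region: str,
             include_tbv: bool):
    covs = [c for c in ARM_A_COVARIATES if include_tbv or c != "tbv"]
    n = len(phenos)
    ones = np.ones(n)
    feh = phenos["feh"].to_numpy(dtype=float)
    sle = phenos["sle"].to_numpy(dtype=float)
    X_med = np.column_stack([ones, feh, sle])
    X_out = np.column_stack([ones, feh, mediator,
                             phenos[list(covs)].to_numpy(dtype=float)])
    y_out = phenos[region].to_numpy(dtype=float)
    return X_med, mediator, X_out, y_out


def _paths(X_med, y_med, X_out, y_out) -> tuple[float, float, float] | None:
    """(a, b, c') from the two fits, or None if either design is deficient."""
    coef_m, _, rank_m, _ = np.linalg.lstsq(X_med, y_med, rcond=None)
    coef_o, _, rank_o, _ = np.linalg.lstsq(X_out, y_out, rcond=None)
    if rank_m < X_med.shape[1] or rank_o < X_out.shape[1]:
        return None
    return coef_m[1], coef_o[2], coef_o[1]  # a, b (ME term), c' (FEH term)


def mediate(
    phenos: pd.DataFrame,
    me: pd.Series,
    region: str,
    treat_value: float | None = None,
    control_value: float | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    include_tbv: bool = True,
    keep_draws: bool = False,
) -> MediationResult:
    """Decompose the FEH effect on a region volume through one mediator."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    phenos = phenos.loc[me.index]
    med = me.to_numpy(dtype=float)
    if med.std() == 0:
        raise ValueError("degenerate (constant) mediator")
    feh = phenos["feh"].to_numpy(dtype=float)
    if treat_value is None:
        treat_value = float(feh.min())
    if control_value is None:
        control_value = float(feh.max())
    if treat_value == control_value:
        raise ValueError("treat and control values must differ")
    delta = treat_value - control_value

    X_med, y_med, X_out, y_out = _designs(phenos, med, region, include_tbv)
    paths = _paths(X_med, y_med, X_out, y_out)
    if paths is None:
        raise np.linalg.LinAlgError("rank-deficient design on the full sample")
    a, b, c = paths
    point = {"IDE": a * b * delta, "DE": c * delta, "TE": (a * b + c) * delta}

    rng = np.random.default_rng(seed)
    n = len(y_out)
    draws = {eff: np.empty(n_boot) for eff in EFFECTS}
    n_redrawn = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            paths_i = _paths(X_med[idx], y_med[idx], X_out[idx], y_out[idx])
            if paths_i is not None:
                break
            n_redrawn += 1
        ai, bi, ci = paths_i
        draws["IDE"][i] = ai * bi * delta
        draws["DE"][i] = ci * delta
        draws["TE"][i] = (ai * bi + ci) * delta

    effects = {}
    for eff in EFFECTS:
        d = draws[eff]
        lo, hi = np.percentile(d, [2.5, 97.5])
        p_lo = (np.sum(d <= 0) + 1) / (n_boot + 1)
        p_hi = (np.sum(d >= 0) + 1) / (n_boot + 1)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        effects[eff] = EffectEstimate(point[eff], float(lo), float(hi), float(p))

    return MediationResult(
        mediator=str(me.name), outcome=region, effects=effects,
        treat_value=treat_value, control_value=control_value,
        n_boot=n_boot, seed=seed, n_redrawn=n_redrawn,
        draws=draws if keep_draws else None,
    )


def classify_mediation(result: MediationResult) -> str:
    """'full' if DE is indistinguishable from 0 while IDE and TE are not;
    'partial' if all three are distinguishable from 0; otherwise 'none'."""
    ide, de, te = result.ide.nonzero, result.de.nonzero, result.te.nonzero
    if ide and te and not de:
        return "full"
    if ide and te and de:
        return "partial"
    return "none"


def proportion_mediated(result: MediationResult) -> float:
    """IDE / TE as a signed fraction of the total effect."""
    te = result.te.estimate
    if te == 0:
        raise ZeroDivisionError("total effect is zero")
    return result.ide.estimate / te


def result_row(result: MediationResult, classification: str | None = None) -> list[dict]:
    if classification is None:
        classification = classify_mediation(result)
    rows = []
    for eff in EFFECTS:
        e = result.effects[eff]
        rows.append({
            "mediator": result.mediator, "outcome": result.outcome,
            "effect": eff, "b": e.estimate,
            "ci_lower": e.ci_lower, "ci_upper": e.ci_upper, "p": e.p,
            "classification": classification,
        })
    return rows


def mediation_screen(
    phenos: pd.DataFrame,
    me_matrix: pd.DataFrame,
    candidates: list[tuple[str, str]],
    n_boot: int = 10_000,
    seed: int = 0,
    fdr: float = 0.10,
    include_tbv: bool = True,
) -> tuple[pd.DataFrame, list[MediationResult]]:
    """Run mediation for every (mediator, region) candidate pair.

    Candidates are the eigengenes that survived all three association arms,
    paired with the region that carried them there. BH correction spans the
    whole family of ``3 x n_candidates`` effect tests (IDE, DE and TE each
    count). Returns the long-format report plus the raw results.
    """
    rows: list[dict] = []
    results: list[MediationResult] = []
    for i, (mname, region) in enumerate(candidates):
        res = mediate(phenos, me_matrix[mname], region,
                      n_boot=n_boot, seed=int(np.random.default_rng([seed, i]).integers(2**31)),
                      include_tbv=include_tbv)
        results.append(res)
        rows.extend(result_row(res))
    report = pd.DataFrame(rows, columns=[
        "mediator", "outcome", "effect", "b",
        "ci_lower", "ci_upper", "p", "classification"])
    if len(report):
        bh = bh_adjust(report["p"], fdr=fdr)
        report["bh_significant"] = bh["significant"].to_numpy()
    else:
        report["bh_significant"] = pd.Series(dtype=bool)
    return report, results


def probe_mediation(
    probe_resid: pd.DataFrame,
    phenos: pd.DataFrame,
    region: str,
    me: pd.Series | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    fdr: float = 0.10,
    include_tbv: bool = True,
) -> tuple[pd.DataFrame, list[MediationResult]]:
    """Probe-level follow-up within a fully mediating module.

    Each probe's residualized M-value replaces the eigengene as mediator;
    the BH family is ``3 x n_probes``. When the module eigengene is given,
    each probe's Pearson correlation with it is reported as a measure of
    how representative the probe is of its module.
    """
    rows: list[dict] = []
    results: list[MediationResult] = []
    for i, probe in enumerate(probe_resid.columns):
        res = mediate(phenos, probe_resid[probe], region,
                      n_boot=n_boot, seed=int(np.random.default_rng([seed, i]).integers(2**31)),
                      include_tbv=include_tbv)
        results.append(res)
        cls = classify_mediation(res)
        r_me = np.nan
        if me is not None:
            r_me = float(np.corrcoef(probe_resid[probe], me.loc[probe_resid.index])[0, 1])
        for row in result_row(res, cls):
            row["r_with_me"] = r_me
            rows.append(row)
    report = pd.DataFrame(rows, columns=[
        "mediator", "outcome", "effect", "b",
        "ci_lower", "ci_upper", "p", "classification", "r_with_me"])
    if len(report):
        bh = bh_adjust(report["p"], fdr=fdr)
        report["bh_significant"] = bh["significant"].to_numpy()
    else:
        report["bh_significant"] = pd.Series(dtype=bool)
    return report, results
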