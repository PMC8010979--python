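"""Methylation preprocessing: beta/M transforms, quantile normalization,
design-based probe filters, and the cross-tissue (saliva-brain) correlation
filter.

The analysis scale throughout the package is the M-value,
``M = log2(beta / (1 - beta))``, which stabilizes the variance of the
bounded beta proportion. Probes on the sex chromosomes, SNP (rs) probes and
optionally cross-hybridizing probes are removed before network construction;
the surviving universe is then restricted to probes whose saliva signal
correlates with a paired brain-tissue reference, so downstream modules are
built only on loci with some prospect of surrogate status for CNS tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def beta_to_m(beta: pd.DataFrame | np.ndarray, eps: float = 1e-6):
    """Logit (base 2) transform of beta values, clipped away from {0, 1}.

    Parameters
    ----------
    beta : samples x probes matrix of proportions.
    eps : clipping bound, ``0 < eps < 0.5``; values are clipped to
        ``[eps, 1 - eps]`` before the transform so M stays finite.
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    vals = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("beta matrix contains non-finite values")
    clipped = np.clip(vals, eps, 1 - eps)
    m = np.log2(clipped / (1 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m: pd.DataFrame | np.ndarray):
    """Inverse of :func:`beta_to_m` (exact away from the clipping bounds)."""
    vals = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + np.power(2.0, -vals))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    return beta


def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (row) onto the mean empirical distribution.

    After normalization each sample's sorted value vector equals the
    across-sample mean of sorted vectors; within-sample ranks are preserved,
    with ties resolved by averaging the reference values they span.
    """
    if beta.shape[0] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = beta.to_numpy(dtype=float)
    n_samp, n_probe = vals.shape
    order = np.sort(vals, axis=1)
    reference = order.mean(axis=0)
    out = np.empty_like(vals)
    # average ranks map ties onto the mean of the reference slots they occupy
    positions = np.arange(1, n_probe + 1, dtype=float)
    for i in range(n_samp):
        ranks = stats.rankdata(vals[i], method="average")
        out[i] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


@dataclass
class FilterReport:
    """Per-reason removal counts from :func:`filter_probes`.

    A probe flagged for several reasons is counted once under each reason
    but removed exactly once, so ``n_removed`` can be smaller than the sum
    of the per-reason counts.
    """

    counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_removed: int = 0
    n_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": k, "count": v} for k, v in self.counts.items()]
        rows.append({"reason": "total_removed", "count": self.n_removed})
        rows.append({"reason": "retained", "count": self.n_retained})
        return pd.DataFrame(rows)


def filter_probes(
    m: pd.DataFrame,
    manifest: pd.DataFrame,
    drop_crosshyb: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop X/Y-chromosome, rs-mapped and (optionally) cross-hybridizing probes.

    ``manifest`` is indexed by probe id with at least the columns
    ``chromosome``, ``is_rs_probe`` and ``is_crosshyb``. Every probe in the
    matrix must be present in the manifest.
    """
    missing = m.columns.difference(manifest.index)
    if len(missing):
        raise KeyError(f"{len(missing)} probes missing from manifest, e.g. {missing[0]!r}")
    sub = manifest.loc[m.columns]
    chrom = sub["chromosome"].astype(str)
    reasons = {
        "chrX": chrom.eq("X"),
        "chrY": chrom.eq("Y"),
        "rs_probe": sub["is_rs_probe"].astype(bool),
    }
    if drop_crosshyb:
        reasons["cross_hybridizing"] = sub["is_crosshyb"].astype(bool)
    drop_mask = np.zeros(m.shape[1], dtype=bool)
    report = FilterReport(n_input=m.shape[1])
    for reason, mask in reasons.items():
        mask = mask.to_numpy()
        report.counts[reason] = int(mask.sum())
        drop_mask |= mask
    report.n_removed = int(drop_mask.sum())
    report.n_retained = report.n_input - report.n_removed
    return m.loc[:, ~drop_mask], report


def pearson_pvalues(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r and two-sided p (t transform, n-2 df).

    ``x`` and ``y`` are paired (n x p) arrays; columns with zero variance in
    either member yield ``r = nan, p = nan``.
    """
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=0) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    bad = (sx == 0) | (sy == 0)
    r[bad] = np.nan
    p[bad] = np.nan
    return r, p


def brain_saliva_filter(
    saliva: pd.DataFrame,
    reference: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.Index, pd.DataFrame]:
    """Retain probes whose saliva values correlate with the paired reference.

    Both matrices are samples x probes with paired rows; only shared probes
    are tested. Returns the retained probe index plus a per-probe table of
    Pearson r and two-sided p. Constant probes (in either tissue) cannot be
    tested and are dropped with a warning.
    """
    shared = saliva.columns.intersection(reference.columns)
    if len(shared) == 0:
        raise ValueError("no shared probes between saliva and reference matrices")
    n = min(saliva.shape[0], reference.shape[0])
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    x = saliva.loc[:, shared].to_numpy(dtype=float)[:n]
    y = reference.loc[:, shared].to_numpy(dtype=float)[:n]
    r, p = pearson_pvalues(x, y)
    table = pd.DataFrame({"r": r, "p": p}, index=shared)
    n_const = int(np.isnan(p).sum())
    if n_const:
        warnings.warn(f"{n_const} constant probes dropped from cross-tissue filter")
    keep = shared[np.nan_to_num(p, nan=1.0) < alpha]
    return keep, table
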