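"""Weighted co-methylation network: residualized M-values, soft-threshold
selection by scale-free fit, signed-free (unsigned) adjacency, topological
overlap dissimilarity, hierarchical module detection, and module eigengenes.

The network follows the weighted co-expression tradition: adjacency is
``|Pearson r|`` raised to a soft power chosen as the lowest power whose
scale-free topology fit exceeds an R^2 threshold; similarity of two probes
is their topological overlap (shared-neighbour weight plus direct
adjacency); modules are branches of an average-linkage tree over
``1 - TOM`` cut at a fixed quantile of merge heights; each module is
summarized by its eigengene, the first principal component of its
standardized probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

# Conventional ordered color sequence for module naming (largest first).
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


def residualize(m: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    """Per-probe OLS residuals after regressing out the covariates.

    An intercept is always included, so with no covariates the result is
    simply mean-centered. Raises on rank-deficient designs and on designs
    with no residual degrees of freedom.
    """
    Y = m.to_numpy(dtype=float)
    n = Y.shape[0]
    if covariates is None or covariates.shape[1] == 0:
        X = np.ones((n, 1))
    else:
        if len(covariates) != n:
            raise ValueError("covariates and matrix disagree on sample count")
        X = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient covariate design")
    if n <= X.shape[1]:
        raise ValueError("more covariate terms than samples")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return pd.DataFrame(resid, index=m.index, columns=m.columns)


def _abs_corr(resid: np.ndarray) -> np.ndarray:
    sd = resid.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant probes produce undefined correlations")
    C = np.corrcoef(resid, rowvar=False)
    return np.abs(np.clip(C, -1.0, 1.0))


@dataclass
class SoftThresholdFit:
    power: float
    fit_table: pd.DataFrame  # power, r2 (signed, adjusted), mean_k, slope
    satisfied: bool


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed adjusted R^2 of the log-log degree-distribution fit.

    Connectivities are binned on their own scale; the frequency per bin is
    regressed on the bin-mean connectivity after log10 transforms. The R^2
    is signed by the negated slope (scale-free topology requires a
    decreasing relationship) and adjusted for the two-parameter fit.
    """
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if len(members) == 0 or members.mean() <= 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(len(members) / len(k)))
    if len(log_k) < 3:
        return 0.0, 0.0
    x, y = np.asarray(log_k), np.asarray(log_p)
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = float(((y - (slope * x + intercept)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    n_pts = len(x)
    adj = 1.0 - (1.0 - r2) * (n_pts - 1) / (n_pts - 2)
    return float(np.sign(-slope) * adj), float(slope)


def pick_soft_threshold(
    resid: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    r2_min: float = 0.90,
) -> SoftThresholdFit:
    """Lowest candidate power whose scale-free fit exceeds ``r2_min``.

    If no candidate reaches the threshold the best-fitting power is
    returned with a warning, mirroring common practice.
    """
    powers = list(candidate_powers)
    if len(powers) < 2:
        raise ValueError("need at least 2 candidate powers")
    if resid.shape[1] < 30:
        raise ValueError("need at least 30 probes for a meaningful fit")
    A0 = _abs_corr(resid.to_numpy(dtype=float))
    np.fill_diagonal(A0, 0.0)
    rows = []
    for beta in powers:
        k = (A0 ** beta).sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"power": beta, "r2": r2, "mean_k": float(k.mean()),
                     "slope": slope})
    table = pd.DataFrame(rows)
    ok = table[table["r2"] > r2_min]
    if len(ok):
        return SoftThresholdFit(float(ok.iloc[0]["power"]), table, True)
    best = table.loc[table["r2"].idxmax()]
    warnings.warn(
        f"no candidate power reached scale-free R^2 > {r2_min}; "
        f"using power {best['power']:g} (R^2 = {best['r2']:.3f})")
    return SoftThresholdFit(float(best["power"]), table, False)


@dataclass
class CoMethNetwork:
    power: float
    adjacency: pd.DataFrame      # |cor|^power, zero diagonal
    dissimilarity: pd.DataFrame  # 1 - TOM, zero diagonal

    @property
    def probes(self) -> pd.Index:
        return self.adjacency.index


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """TOM from an adjacency with zero diagonal.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` and unit diagonal.
    """
    k = A.sum(axis=1)
    L = A @ A  # zero diagonal makes u = i, j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def build_network(resid: pd.DataFrame, power: float) -> CoMethNetwork:
    """Unsigned weighted network and its topological-overlap dissimilarity."""
    if power <= 0:
        raise ValueError("power must be positive")
    A = _abs_corr(resid.to_numpy(dtype=float)) ** power
    np.fill_diagonal(A, 0.0)
    D = 1.0 - topological_overlap(A)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)  # symmetrize fp noise
    probes = resid.columns
    return CoMethNetwork(
        power=float(power),
        adjacency=pd.DataFrame(A, index=probes, columns=probes),
        dissimilarity=pd.DataFrame(D, index=probes, columns=probes),
    )


@dataclass
class ModuleSet:
    labels: pd.Series        # probe -> module index (0 = unassigned)
    names: dict[int, str]    # module index -> color name

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def members(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "module_index": self.labels,
            "module_name": [self.names.get(v, "unassigned") for v in self.labels],
        })


def detect_modules(
    network: CoMethNetwork,
    min_size: int = 10,
    cut_height: float = 0.98,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static cut.

    The tree is cut at a fixed height on the dissimilarity scale (default
    0.98): correlated probes merge far below it while unrelated probes sit
    near 1, so background stays unclustered. Clusters smaller than
    ``min_size`` dissolve to the unassigned label 0. Surviving modules are
    renumbered 1, 2, ... by descending size (ties broken by the
    lexicographically smallest member probe id) and named from a fixed
    color palette.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not 0 < cut_height <= 1:
        raise ValueError("cut_height must lie in (0, 1]")
    probes = network.probes
    n = len(probes)
    if n < min_size:
        labels = pd.Series(0, index=probes, name="module")
        return ModuleSet(labels, {})
    # order-invariant input: cluster on a canonical (sorted) probe order
    order = np.argsort(probes.to_numpy())
    D = network.dissimilarity.to_numpy()[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=float(cut_height), criterion="distance")

    sorted_probes = probes.to_numpy()[order]
    sizes: dict[int, int] = {}
    first_probe: dict[int, str] = {}
    for lab, pid in zip(raw, sorted_probes):
        sizes[lab] = sizes.get(lab, 0) + 1
        first_probe.setdefault(lab, pid)
    kept = [lab for lab, s in sizes.items() if s >= min_size]
    kept.sort(key=lambda lab: (-sizes[lab], first_probe[lab]))
    relabel = {lab: i + 1 for i, lab in enumerate(kept)}

    final = np.zeros(n, dtype=int)
    for i, lab in enumerate(raw):
        final[i] = relabel.get(lab, 0)
    labels = pd.Series(final, index=sorted_probes, name="module").reindex(probes)
    names = {i + 1: MODULE_COLORS[i % len(MODULE_COLORS)] for i in range(len(kept))}
    return ModuleSet(labels, names)


def module_eigengenes(resid: pd.DataFrame, modules: ModuleSet) -> pd.DataFrame:
    """First-principal-component sample scores per module (unit variance).

    Probes are standardized before the SVD; the eigengene's sign is fixed
    so its mean correlation with the module's probes is positive, making
    results reproducible across linear-algebra backends.
    """
    out = {}
    for mid in modules.module_ids:
        members = modules.members(mid)
        missing = members.difference(resid.columns)
        if len(missing):
            raise KeyError(f"module {mid} probes missing from matrix: {list(missing)[:3]}")
        X = resid.loc[:, members].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError(f"module {mid} contains a constant probe")
        Xs = (X - X.mean(axis=0)) / sd
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        me = U[:, 0]
        me = me / me.std(ddof=1)
        corrs = np.array([np.corrcoef(me, Xs[:, j])[0, 1] for j in range(Xs.shape[1])])
        if corrs.mean() < 0:
            me = -me
        name = modules.names.get(mid, f"module{mid}")
        out[name] = me
    return pd.DataFrame(out, index=resid.index)


def variance_explained(resid: pd.DataFrame, members: pd.Index,
                       scores: np.ndarray) -> float:
    """Fraction of standardized module variance captured by a score vector."""
    X = resid.loc[:, members].to_numpy(dtype=float)
    r = np.array([np.corrcoef(scores, X[:, j])[0, 1] for j in range(X.shape[1])])
    return float(np.mean(r ** 2))
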