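"""Reference-free cell-type deconvolution of saliva methylation.

Bulk saliva beta values are modelled as a convex mixture of K latent
cell-type profiles, ``Y ~ P @ F.T`` with sample proportions ``P`` on the
simplex and probe profiles ``F`` in [0, 1]. Proportions are estimated by
alternating constrained least squares on the most variable probes and used
downstream as covariates for cellular heterogeneity. K defaults to five,
the value appropriate for saliva.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls


def select_variable_probes(beta: pd.DataFrame, k: int) -> pd.Index:
    """The k probes with largest across-sample variance.

    Ties are broken deterministically by probe id (lexicographic), so the
    selection is stable across runs and input orderings.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > beta.shape[1]:
        raise ValueError(f"k={k} exceeds probe count {beta.shape[1]}")
    var = beta.var(axis=0, ddof=1)
    order = sorted(beta.columns, key=lambda pid: (-var[pid], pid))
    return pd.Index(order[:k])


@dataclass
class CellMixture:
    """Estimated mixture: proportions (samples x K, rows on the simplex),
    profiles (probes x K in [0, 1]), and the achieved reconstruction error
    (Frobenius norm of the residual)."""

    proportions: pd.DataFrame
    profiles: pd.DataFrame
    reconstruction_error: float
    n_iter: int
    converged: bool
    error_path: list[float] = None  # accepted-iterate errors, best restart

    @property
    def k(self) -> int:
        return self.proportions.shape[1]


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, len(v) + 1) > 0)[0][-1]
    theta = (1.0 - css[rho]) / (rho + 1.0)
    return np.maximum(v + theta, 0.0)


def _solve_proportions(F: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-sample non-negative least squares, projected onto the simplex."""
    n = Y.shape[0]
    P = np.empty((n, F.shape[1]))
    for i in range(n):
        p, _ = nnls(F, Y[i])
        P[i] = _project_simplex(p)
    return P


def estimate_cell_mixture(
    beta_subset: pd.DataFrame,
    k: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 10,
) -> CellMixture:
    """Alternating constrained least squares for the mixture model.

    Given proportions, profiles are solved probe-wise by least squares and
    clipped to [0, 1]; given profiles, each sample's proportions are solved
    by non-negative least squares and projected onto the simplex. Iteration
    stops when the relative Frobenius improvement drops below ``tol`` (or an
    iterate fails to improve, in which case the previous iterate is kept, so
    the reported error is non-increasing along the accepted path). The
    objective is non-convex, so the fit restarts from ``n_restarts``
    Dirichlet initializations and keeps the lowest reconstruction error.

    Components are relabelled by descending mean proportion for
    deterministic output.
    """
    Y = beta_subset.to_numpy(dtype=float)
    n, p = Y.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n_samples, n_probes)={min(n, p)}")
    if k > np.linalg.matrix_rank(Y):
        warnings.warn(f"k={k} exceeds the numerical rank of the data")

    if k == 1:
        P = np.ones((n, 1))
        F = np.clip(Y.mean(axis=0), 0.0, 1.0)[:, None]
        err = float(np.linalg.norm(Y - P @ F.T))
        return _package(P, F, err, 0, True, [err], beta_subset)

    root = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(root.integers(2**31))
        P = rng.dirichlet(np.ones(k), n)
        prev_err = np.inf
        P_best, F_best, err_best, it_used, converged = P, None, np.inf, 0, False
        path: list[float] = []
        for it in range(1, max_iter + 1):
            F = np.clip(np.linalg.lstsq(P, Y, rcond=None)[0].T, 0.0, 1.0)
            P_new = _solve_proportions(F, Y)
            err = float(np.linalg.norm(Y - P_new @ F.T))
            if err > prev_err:      # projection overshoot: keep prior iterate
                break
            P, it_used = P_new, it
            path.append(err)
            if err < err_best:
                P_best, F_best, err_best = P, F, err
            if prev_err - err < tol * max(prev_err, 1.0):
                converged = True
                break
            prev_err = err
        if F_best is None:          # first iteration already failed to improve
            F_best = np.clip(np.linalg.lstsq(P, Y, rcond=None)[0].T, 0.0, 1.0)
            err_best = float(np.linalg.norm(Y - P @ F_best.T))
            P_best = P
            path = [err_best]
        if best is None or err_best < best[2]:
            best = (P_best, F_best, err_best, it_used, converged, path)

    P, F, err, n_iter, converged, path = best
    if not converged:
        warnings.warn("deconvolution did not converge; best iterate returned")
    return _package(P, F, err, n_iter, converged, path, beta_subset)


def _package(P, F, err, n_iter, converged, path, beta_subset) -> CellMixture:
    order = np.argsort(-P.mean(axis=0))
    P, F = P[:, order], F[:, order]
    cols = [f"cell{j + 1}" for j in range(P.shape[1])]
    return CellMixture(
        proportions=pd.DataFrame(P, index=beta_subset.index, columns=cols),
        profiles=pd.DataFrame(F, index=beta_subset.columns, columns=cols),
        reconstruction_error=err,
        n_iter=n_iter,
        converged=converged,
        error_path=path,
    )
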