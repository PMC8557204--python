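"""Unregularized Gaussian graphical models on Spearman correlations.

A Gaussian graphical model (GGM) encodes conditional-independence structure
in the zeros of the precision matrix K: nodes i and j share an edge iff
K_ij != 0, and the edge weight is the partial correlation

    w_ij = -K_ij / sqrt(K_ii * K_jj).

This module provides rank-based (Spearman) correlation estimation, the
maximum-likelihood fit of a Gaussian model under a fixed zero pattern
(iterative proportional fitting over node neighbourhoods), the extended
Bayesian information criterion (EBIC), and a stepwise structure search that
selects the EBIC-optimal unregularized model: a thresholded start path over
the sample partial correlations followed by greedy single-edge additions and
removals until no move lowers the EBIC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "GGMFit",
    "spearman_corr",
    "partial_from_precision",
    "fit_constrained_ggm",
    "ebic",
    "model_search",
]

# eigenvalue floor used when repairing indefinite rank-based correlation matrices
_EIG_FLOOR = 1e-6


@dataclass
class CorrelationMatrix:
    """A symmetric unit-diagonal correlation matrix with provenance."""

    matrix: np.ndarray
    n_effective: int
    method: str = "spearman"
    labels: list[str] | None = None

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GGMFit:
    """Constrained Gaussian MLE: structure, precision, partial-correlation weights.

    ``structure`` is a boolean adjacency matrix; ``precision`` is exactly zero
    off-structure. ``weights`` holds the partial correlations used as edge
    weights everywhere downstream.
    """

    structure: np.ndarray
    precision: np.ndarray
    weights: np.ndarray
    loglik: float
    ebic: float
    gamma: float
    n: int
    p: int
    labels: list[str] | None = None
    n_sweeps: int = 0
    fitted_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.structure, 1).sum())

    def edge_list(self) -> pd.DataFrame:
        """Edges as a tidy frame: node_i, node_j, weight."""
        labels = self.labels or [str(i) for i in range(self.p)]
        rows = []
        for i, j in zip(*np.triu_indices(self.p, 1)):
            if self.structure[i, j]:
                rows.append((labels[i], labels[j], float(self.weights[i, j])))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels or [str(i) for i in range(self.p)],
                "structure": self.structure.astype(int).tolist(),
                "weights": self.weights.tolist(),
                "loglik": self.loglik,
                "ebic": self.ebic,
                "gamma": self.gamma,
                "n": self.n,
                "p": self.p,
            },
            indent=1,
        )


def spearman_corr(data, missing_policy: str = "listwise") -> CorrelationMatrix:
    """Spearman rank correlation matrix with listwise deletion.

    Ties receive average ranks; the product-moment correlation of the ranks is
    returned. Raises on constant columns (their rank correlation is undefined),
    naming the offending column.
    """
    if missing_policy != "listwise":
        raise ValueError(f"unsupported missing_policy: {missing_policy!r}")
    df = pd.DataFrame(data)
    labels = [str(c) for c in df.columns]
    complete = df.dropna(axis=0, how="any")
    n = len(complete)
    if n < 3:
        raise ValueError(f"need >= 3 complete rows, got {n}")
    values = complete.to_numpy(dtype=float)
    for k, lab in enumerate(labels):
        if np.ptp(values[:, k]) == 0:
            raise ValueError(f"constant column: {lab!r}")
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    R = np.corrcoef(ranks, rowvar=False)
    R = np.asarray(R, dtype=float)
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    return CorrelationMatrix(matrix=R, n_effective=n, method="spearman", labels=labels)


def repair_correlation(R: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and re-standardize to unit diagonal.

    Rank-based correlation matrices can be indefinite under awkward
    missing-data patterns; the repaired matrix is the nearest-in-spirit PD
    correlation matrix obtained by spectral clipping.
    """
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    if w.min() > floor:
        return R
    w = np.clip(w, floor, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2.0


def partial_from_precision(K: np.ndarray) -> np.ndarray:
    """Partial correlations w_ij = -K_ij / sqrt(K_ii K_jj), zero diagonal."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    try:
        np.linalg.cholesky((K + K.T) / 2.0)
    except np.linalg.LinAlgError as exc:
        raise ValueError("K must be positive definite") from exc
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


class GGMConvergenceError(RuntimeError):
    """IPS failed to converge; carries iteration diagnostics."""

    def __init__(self, message: str, n_sweeps: int, last_delta: float):
        super().__init__(f"{message} (sweeps={n_sweeps}, last_delta={last_delta:.3g})")
        self.n_sweeps = n_sweeps
        self.last_delta = last_delta


def _ips_cov(
    S: np.ndarray,
    adj: np.ndarray,
    W0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> tuple[np.ndarray, int]:
    """Iterative proportional fitting of the constrained Gaussian MLE.

    Cycles over nodes, solving each node's regression on its graph neighbours
    against the current fitted covariance W (the modified-regression form of
    IPS). At convergence W agrees with S on the diagonal and on every edge,
    and W^{-1} is exactly zero off-structure.
    """
    p = S.shape[0]
    W = S.copy() if W0 is None else W0.copy()
    np.fill_diagonal(W, np.diag(S))
    others = [np.array([k for k in range(p) if k != j]) for j in range(p)]
    nbrs = [np.flatnonzero(adj[j]) for j in range(p)]
    last_delta = np.inf
    for sweep in range(1, max_iter + 1):
        delta = 0.0
        for j in range(p):
            oth = others[j]
            nb = nbrs[j]
            if nb.size == 0:
                new = np.zeros(oth.size)
            else:
                # positions of the neighbours inside the "not j" ordering
                pos = np.searchsorted(oth, nb)
                W11 = W[np.ix_(oth, oth)]
                beta_nb = np.linalg.solve(W11[np.ix_(pos, pos)], S[nb, j])
                new = W11[:, pos] @ beta_nb
            old = W[oth, j]
            d = np.abs(new - old).max() if oth.size else 0.0
            if d > delta:
                delta = d
            W[oth, j] = new
            W[j, oth] = new
        last_delta = delta
        if delta < tol:
            return W, sweep
    raise GGMConvergenceError("IPS did not converge", max_iter, last_delta)


def _precision_from_cov(
    S: np.ndarray, W: np.ndarray, adj: np.ndarray
) -> np.ndarray:
    """Recover K = W^{-1} nodewise with exact structural zeros."""
    p = S.shape[0]
    K = np.zeros_like(W)
    for j in range(p):
        oth = np.array([k for k in range(p) if k != j])
        nb = np.flatnonzero(adj[j])
        if nb.size == 0:
            K[j, j] = 1.0 / S[j, j]
            continue
        pos = np.searchsorted(oth, nb)
        W11 = W[np.ix_(oth, oth)]
        beta_nb = np.linalg.solve(W11[np.ix_(pos, pos)], S[nb, j])
        k22 = 1.0 / (S[j, j] - S[nb, j] @ beta_nb)
        K[j, j] = k22
        K[nb, j] = -beta_nb * k22
    K = (K + K.T) / 2.0
    off = ~adj & ~np.eye(p, dtype=bool)
    K[off] = 0.0
    return K


def gaussian_loglik(K: np.ndarray, S: np.ndarray, n: int) -> float:
    """Multivariate-normal log-likelihood l(K) = (n/2)(log det K - tr(SK) - p log 2 pi)."""
    p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision matrix is not positive definite")
    return 0.5 * n * (logdet - float(np.sum(S * K)) - p * np.log(2 * np.pi))


def ebic_score(loglik: float, n_edges: int, n: int, p: int, gamma: float) -> float:
    """EBIC = -2 l + |E| log n + 4 |E| gamma log p."""
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)


def fit_constrained_ggm(
    R: CorrelationMatrix | np.ndarray,
    structure: np.ndarray,
    gamma: float = 0.5,
    n: int | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
    W0: np.ndarray | None = None,
) -> GGMFit:
    """Gaussian MLE under a fixed edge structure.

    The fitted covariance matches the sample matrix exactly on the diagonal and
    on every edge (the moment-matching property of the constrained Gaussian
    MLE); the precision matrix is exactly zero off-structure.
    """
    if isinstance(R, CorrelationMatrix):
        S = repair_correlation(R.matrix)
        if n is None:
            n = R.n_effective
        labels = R.labels
    else:
        S = repair_correlation(np.asarray(R, dtype=float))
        labels = None
    if n is None:
        raise ValueError("sample size n required when R is a bare matrix")
    adj = np.asarray(structure, dtype=bool)
    if not np.array_equal(adj, adj.T):
        raise ValueError("structure must be symmetric")
    adj = adj & ~np.eye(adj.shape[0], dtype=bool)
    p = S.shape[0]
    if adj[~np.eye(p, dtype=bool)].all():
        W, sweeps = S.copy(), 0  # saturated model: MLE is the sample matrix
    else:
        W, sweeps = _ips_cov(S, adj, W0=W0, tol=tol, max_iter=max_iter)
    K = _precision_from_cov(S, W, adj)
    ll = gaussian_loglik(K, S, n)
    n_edges = int(np.triu(adj, 1).sum())
    return GGMFit(
        structure=adj,
        precision=K,
        weights=partial_from_precision(K),
        loglik=ll,
        ebic=ebic_score(ll, n_edges, n, p, gamma),
        gamma=gamma,
        n=n,
        p=p,
        labels=labels,
        n_sweeps=sweeps,
        fitted_cov=W,
    )


def ebic(fit: GGMFit, gamma: float | None = None) -> float:
    """EBIC of a fit, optionally re-evaluated at a different gamma."""
    g = fit.gamma if gamma is None else gamma
    return ebic_score(fit.loglik, fit.n_edges, fit.n, fit.p, g)


def _sample_partials(S: np.ndarray) -> np.ndarray:
    K = np.linalg.inv(repair_correlation(S))
    return partial_from_precision(K)


def model_search(
    R: CorrelationMatrix | np.ndarray,
    gamma: float = 0.5,
    n: int | None = None,
    n_thresholds: int = 40,
    candidate_tol: float = 1e-7,
    final_tol: float = 1e-10,
    max_iter: int = 1000,
    verbose: bool = False,
) -> GGMFit:
    """Stepwise EBIC selection of the unregularized GGM.

    Two phases: (1) a start path thresholding the sample partial correlations
    over a geometric grid, scoring each implied structure by constrained MLE +
    EBIC; (2) greedy refinement evaluating every single-edge addition and
    removal and applying the best strict EBIC decrease until none exists. The
    returned model is therefore a single-edge-local EBIC optimum. Ties within
    1e-10 prefer removals, then the lexicographically smallest node pair.
    """
    if isinstance(R, CorrelationMatrix):
        S = repair_correlation(R.matrix)
        n_eff = R.n_effective if n is None else n
        labels = R.labels
    else:
        S = repair_correlation(np.asarray(R, dtype=float))
        n_eff = n
        labels = None
    if n_eff is None:
        raise ValueError("sample size n required when R is a bare matrix")
    p = S.shape[0]
    if n_eff <= p:
        raise ValueError(
            f"model search requires more observations than nodes (n={n_eff}, p={p})"
        )

    def fit_struct(adj, W0=None, tol=candidate_tol):
        return fit_constrained_ggm(
            S, adj, gamma=gamma, n=n_eff, tol=tol, max_iter=max_iter, W0=W0
        )

    # --- phase 1: thresholded start path over sample partial correlations
    P = _sample_partials(S)
    absvals = np.abs(P[np.triu_indices(p, 1)])
    nonzero = absvals[absvals > 1e-12]
    best = fit_struct(np.zeros((p, p), dtype=bool))  # empty model always scored
    if nonzero.size:
        lo, hi = nonzero.min(), nonzero.max()
        grid = np.geomspace(max(lo, 1e-8), hi, n_thresholds)
        seen = set()
        prev_W = None
        for thr in grid[::-1]:  # densest last so warm starts flow sparse->dense
            adj = np.abs(P) >= thr
            np.fill_diagonal(adj, False)
            key = adj.tobytes()
            if key in seen:
                continue
            seen.add(key)
            try:
                f = fit_struct(adj, W0=prev_W)
            except GGMConvergenceError:
                continue
            prev_W = f.fitted_cov
            if f.ebic < best.ebic:
                best = f
    current = fit_struct(best.structure, W0=best.fitted_cov, tol=final_tol)

    # --- phase 2: greedy single-edge refinement
    visited = {current.structure.tobytes()}
    pairs = list(zip(*np.triu_indices(p, 1)))
    while True:
        cands = []
        for i, j in pairs:
            adj = current.structure.copy()
            removal = adj[i, j]
            adj[i, j] = adj[j, i] = not adj[i, j]
            try:
                f = fit_struct(adj, W0=current.fitted_cov)
            except (GGMConvergenceError, np.linalg.LinAlgError):
                continue
            cands.append((f.ebic, 0 if removal else 1, (int(i), int(j)), f))
        if not cands:
            break
        best_ebic = min(c[0] for c in cands)
        if best_ebic >= current.ebic - 1e-10:
            break
        tied = [c for c in cands if c[0] <= best_ebic + 1e-10]
        tied.sort(key=lambda c: (c[1], c[2]))
        chosen = tied[0][3]
        key = chosen.structure.tobytes()
        if key in visited:
            break  # cycling guard
        visited.add(key)
        current = fit_struct(chosen.structure, W0=chosen.fitted_cov, tol=final_tol)
        if verbose:
            print(f"edges={current.n_edges} ebic={current.ebic:.3f}")
    if labels is not None:
        current.labels = labels
    return current
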