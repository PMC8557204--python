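"""Independent oracles used to validate the estimation path.

These deliberately avoid the package's own algorithms: the constrained MLE is
recovered by generic numerical optimization of the Gaussian log-likelihood
over the free entries of the precision matrix, and partial correlations by
the residual-regression definition.
"""

import numpy as np
from scipy import optimize


def constrained_mle_oracle(S: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """Maximize log det K - tr(SK) over K with zeros off the edge structure."""
    p = S.shape[0]
    free = [(i, i) for i in range(p)] + [
        (i, j) for i in range(p) for j in range(i + 1, p) if adj[i, j]
    ]

    def unpack(x):
        K = np.zeros((p, p))
        for v, (i, j) in zip(x, free):
            K[i, j] = v
            K[j, i] = v
        return K

    def fun(x):
        K = unpack(x)
        w, V = np.linalg.eigh(K)
        if w.min() < 1e-8:
            # smooth push back toward the PD cone (hard walls stall the
            # line search); gradient of the smallest eigenvalue is v v^T
            v = V[:, 0]
            val = 1e6 * (1e-8 - w.min()) + 1e3
            G = -1e6 * np.outer(v, v)
            grad = np.array([G[i, j] * (1.0 if i == j else 2.0) for i, j in free])
            return val, grad
        logdet = float(np.sum(np.log(w)))
        val = -(logdet - float(np.sum(S * K)))
        G = -(np.linalg.inv(K) - S)  # d(-obj)/dK
        grad = np.array([G[i, j] * (1.0 if i == j else 2.0) for i, j in free])
        return val, grad

    x0 = np.array([1.0 if i == j else 0.0 for i, j in free])
    res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return unpack(res.x)


def partial_corr_residual(x: np.ndarray, y: np.ndarray, Z: np.ndarray) -> float:
    """Partial correlation of x and y given Z via residual regression."""
    Z1 = np.column_stack([np.ones(len(x)), Z])
    rx = x - Z1 @ np.linalg.lstsq(Z1, x, rcond=None)[0]
    ry = y - Z1 @ np.linalg.lstsq(Z1, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def random_pd_correlation(p: int, rng: np.random.Generator) -> np.ndarray:
    """Random well-conditioned correlation matrix."""
    A = rng.standard_normal((p, p + 3))
    S = A @ A.T + 0.5 * p * np.eye(p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def random_structure(p: int, rng: np.random.Generator, density: float = 0.5):
    adj = np.zeros((p, p), dtype=bool)
    for i in range(p):
        for j in range(i + 1, p):
            adj[i, j] = adj[j, i] = rng.random() < density
    return adj
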