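"""Node-level and whole-network descriptives for partial-correlation networks.

Expected influence (one-step signed strength) is the centrality of choice for
networks whose edges can be negative; predictability is the share of a node's
variance explained by its graph neighbours; the small-world index omega
contrasts the observed clustering and path length against ring-lattice and
degree-preserving random references (omega near 0: small-world; < 0:
lattice-like; > 0: random-like).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "expected_influence",
    "predictability",
    "density",
    "degree_distribution",
    "small_world_omega",
    "fr_layout",
    "node_metrics_table",
]


def _check_weights(weights: np.ndarray) -> np.ndarray:
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if not np.allclose(np.diag(W), 0.0, atol=1e-12):
        raise ValueError("weight matrix must have a zero diagonal")
    return (W + W.T) / 2.0


def expected_influence(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-step expected influence: raw_i = sum_j w_ij, plus across-node z-scores.

    When all raw values coincide the z-score is undefined; zeros are returned
    with a warning.
    """
    W = _check_weights(weights)
    raw = W.sum(axis=1)
    sd = raw.std(ddof=0)
    if sd == 0:
        warnings.warn("expected influence identical for all nodes; z-scores set to 0")
        return raw, np.zeros_like(raw)
    return raw, (raw - raw.mean()) / sd


def predictability(data, structure: np.ndarray) -> np.ndarray:
    """Per-node R^2 from ordinary least squares on the node's graph neighbours.

    Isolated nodes get 0 by definition. Complete-case data only.
    """
    X = pd.DataFrame(data).dropna(axis=0, how="any").to_numpy(dtype=float)
    adj = np.asarray(structure, dtype=bool)
    n, p = X.shape
    if adj.shape != (p, p):
        raise ValueError("structure shape does not match data columns")
    Xc = X - X.mean(axis=0)
    out = np.zeros(p)
    for j in range(p):
        nb = np.flatnonzero(adj[j] & (np.arange(p) != j))
        if nb.size == 0:
            continue
        if nb.size >= n:
            raise ValueError(f"node {j} has {nb.size} neighbours but only {n} rows")
        y = Xc[:, j]
        tss = float(y @ y)
        if tss == 0:
            continue
        coef, *_ = np.linalg.lstsq(Xc[:, nb], y, rcond=None)
        resid = y - Xc[:, nb] @ coef
        out[j] = max(0.0, 1.0 - float(resid @ resid) / tss)
    return out


def density(structure: np.ndarray) -> float:
    """Fraction of possible edges present."""
    adj = np.asarray(structure, dtype=bool)
    p = adj.shape[0]
    if p < 2:
        return 0.0
    return float(np.triu(adj, 1).sum() / (p * (p - 1) / 2))


def degree_distribution(structure: np.ndarray) -> np.ndarray:
    """Histogram of node degrees: entry d counts nodes with degree d."""
    adj = np.asarray(structure, dtype=bool)
    np.fill_diagonal(adj := adj.copy(), False)
    deg = adj.sum(axis=1)
    return np.bincount(deg, minlength=1)


def _ring_lattice(p: int, m: int) -> nx.Graph:
    """Ring lattice on p nodes with exactly m edges.

    Full nearest-neighbour rings are added offset by offset; leftover edges go
    to the next offset starting from node 0.
    """
    G = nx.empty_graph(p)
    remaining = m
    offset = 1
    while remaining > 0 and offset <= p // 2:
        ring = p if (offset < p / 2) else p // 2  # antipodal offset has p/2 edges
        if remaining >= ring:
            for i in range(p):
                G.add_edge(i, (i + offset) % p)
            remaining = m - G.number_of_edges()
        else:
            for i in range(p):
                if G.number_of_edges() >= m:
                    break
                G.add_edge(i, (i + offset) % p)
            remaining = 0
        offset += 1
    return G


def small_world_omega(
    structure: np.ndarray, n_ref: int = 100, seed: int = 0
) -> float:
    """Small-world omega = L_rand / L - C / C_latt on the binarized graph.

    L and C are the characteristic path length and mean clustering coefficient
    of the observed graph (largest connected component, with a warning, if
    disconnected); L_rand averages over ``n_ref`` degree-preserving rewirings;
    C_latt comes from a ring lattice with matched node and edge counts.
    """
    adj = np.asarray(structure) != 0
    np.fill_diagonal(adj := adj.copy(), False)
    G = nx.from_numpy_array(adj.astype(int))
    if not nx.is_connected(G):
        warnings.warn("graph disconnected; omega computed on the largest component")
        G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
        G = nx.convert_node_labels_to_integers(G)
    p, m = G.number_of_nodes(), G.number_of_edges()
    if m < 2 or p < 4:
        raise ValueError("graph too sparse for small-world references")
    C = nx.average_clustering(G)
    L = nx.average_shortest_path_length(G)
    if density(nx.to_numpy_array(G) != 0) == 1.0:
        return 0.0  # complete graph: all references coincide
    latt = _ring_lattice(p, m)
    C_latt = nx.average_clustering(latt)
    if C_latt == 0:
        raise ValueError("matched ring lattice has zero clustering; graph too sparse")
    rng = np.random.default_rng(seed)
    L_rands = []
    for _ in range(n_ref):
        H = G.copy()
        try:
            nx.double_edge_swap(
                H,
                nswap=4 * m,
                max_tries=400 * m,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXError:
            pass  # too few swappable pairs; use the graph as-is
        if nx.is_connected(H):
            L_rands.append(nx.average_shortest_path_length(H))
        else:
            comp = H.subgraph(max(nx.connected_components(H), key=len))
            L_rands.append(nx.average_shortest_path_length(comp))
    L_rand = float(np.mean(L_rands))
    return float(L_rand / L - C / C_latt)


def fr_layout(
    weights: np.ndarray, seed: int = 0, iterations: int = 200
) -> dict[int, np.ndarray]:
    """Fruchterman-Reingold coordinates with |weight| as attraction strength.

    Strongly connected nodes land close together and centrally; deterministic
    under a fixed seed.
    """
    W = _check_weights(weights)
    if W.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    G = nx.from_numpy_array(np.abs(W))
    return nx.spring_layout(G, seed=seed, iterations=iterations, weight="weight")


def node_metrics_table(
    weights: np.ndarray,
    data=None,
    structure: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Bundle per-node metrics into one table (the shape figures are drawn from)."""
    W = _check_weights(weights)
    p = W.shape[0]
    adj = (W != 0) if structure is None else np.asarray(structure, dtype=bool)
    raw, z = expected_influence(W)
    table = pd.DataFrame(
        {
            "expected_influence_raw": raw,
            "expected_influence_z": z,
            "degree": adj.sum(axis=1).astype(int),
        },
        index=labels if labels is not None else range(p),
    )
    if data is not None:
        table["predictability"] = predictability(data, adj)
    return table
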