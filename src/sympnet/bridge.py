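"""Bridge centrality between a-priori node communities.

With symptoms and disease clusters designated as two communities, a node's
bridge expected influence is the signed sum of its edges into the other
community, and its network cross-loading is an effect-size-style standardized
version of its connection mass into that community. Both identify the
symptoms through which somatic burden enters the depressive network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import _check_weights

__all__ = [
    "bridge_expected_influence",
    "network_cross_loadings",
    "classify_loading_magnitude",
    "bridge_edge_report",
    "DEFAULT_LOADING_CUTOFFS",
]

# |loading| bins: below small -> negligible; class assigned when |x| >= cutoff
DEFAULT_LOADING_CUTOFFS = (0.15, 0.25, 0.35)


def _check_communities(labels: list, communities: dict) -> list:
    missing = [l for l in labels if l not in communities]
    if missing:
        raise ValueError(f"nodes without a community label: {missing}")
    groups = sorted(set(communities[l] for l in labels))
    if len(groups) < 2:
        raise ValueError("bridge metrics require at least 2 communities")
    return groups


def bridge_expected_influence(
    weights: np.ndarray,
    communities: dict,
    labels: list | None = None,
) -> pd.DataFrame:
    """One-step bridge expected influence per node.

    raw_i sums w_ij over neighbours j in *other* communities; z-scores are
    computed across nodes within each community, so symptom and disease nodes
    are each ranked against their own kind.
    """
    W = _check_weights(weights)
    p = W.shape[0]
    labels = list(labels) if labels is not None else list(range(p))
    _check_communities(labels, communities)
    comm = np.array([communities[l] for l in labels])
    raw = np.array(
        [float(W[i, comm != comm[i]].sum()) for i in range(p)]
    )
    z = np.zeros(p)
    for g in np.unique(comm):
        idx = comm == g
        sd = raw[idx].std(ddof=0)
        if sd > 0:
            z[idx] = (raw[idx] - raw[idx].mean()) / sd
    return pd.DataFrame(
        {"community": comm, "bridge_ei_raw": raw, "bridge_ei_z": z}, index=labels
    )


def network_cross_loadings(
    weights: np.ndarray,
    communities: dict,
    labels: list | None = None,
    cutoffs: tuple[float, float, float] = DEFAULT_LOADING_CUTOFFS,
) -> pd.DataFrame:
    """Standardized loading of every node on every foreign community.

    Raw loading of node i on community c is the summed |w_ij| over j in c,
    signed by the dominant edge sign; the standardized loading divides by the
    square root of c's total absolute cross-community loading mass. The exact
    normalization is echoed in the frame's ``attrs`` so outputs are
    self-describing.
    """
    W = _check_weights(weights)
    p = W.shape[0]
    labels = list(labels) if labels is not None else list(range(p))
    groups = _check_communities(labels, communities)
    comm = np.array([communities[l] for l in labels])
    for g in groups:
        if not (comm == g).any():
            raise ValueError(f"empty community: {g}")
    mass = {
        g: float(np.abs(W[np.ix_(comm != g, comm == g)]).sum()) for g in groups
    }
    rows = []
    for i in range(p):
        for g in groups:
            if g == comm[i]:
                continue
            w = W[i, comm == g]
            raw_abs = float(np.abs(w).sum())
            sign = 1.0 if w.sum() >= 0 else -1.0
            raw = sign * raw_abs
            std = raw / np.sqrt(mass[g]) if mass[g] > 0 else 0.0
            rows.append(
                (
                    labels[i],
                    comm[i],
                    g,
                    raw,
                    std,
                    classify_loading_magnitude(std, cutoffs),
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "node",
            "community",
            "foreign_community",
            "raw_loading",
            "standardized_loading",
            "magnitude_class",
        ],
    )
    out.attrs["formula"] = (
        "raw = sign(sum w_ij) * sum_j_in_c |w_ij|; "
        "standardized = raw / sqrt(sum over foreign i of sum_j_in_c |w_ij|)"
    )
    out.attrs["cutoffs"] = tuple(cutoffs)
    return out


def classify_loading_magnitude(
    loading: float, cutoffs: tuple[float, float, float] = DEFAULT_LOADING_CUTOFFS
) -> str:
    """Bin |loading| against ascending cutoffs (class assigned when |x| >= cutoff)."""
    small, moderate, large = cutoffs
    if not (small < moderate < large):
        raise ValueError("cutoffs must be strictly ascending")
    x = abs(float(loading))
    if x >= large:
        return "large"
    if x >= moderate:
        return "moderate"
    if x >= small:
        return "small"
    return "negligible"


def bridge_edge_report(
    weights: np.ndarray, communities: dict, labels: list | None = None
) -> pd.DataFrame:
    """Every nonzero cross-community edge with its weight (bridge connections)."""
    W = _check_weights(weights)
    p = W.shape[0]
    labels = list(labels) if labels is not None else list(range(p))
    _check_communities(labels, communities)
    comm = [communities[l] for l in labels]
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            if comm[i] != comm[j] and W[i, j] != 0:
                rows.append((labels[i], comm[i], labels[j], comm[j], float(W[i, j])))
    return pd.DataFrame(
        rows, columns=["node_i", "community_i", "node_j", "community_j", "weight"]
    )
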