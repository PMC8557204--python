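"""Synthetic cohorts with known ground-truth network structure.

Downstream estimators are validated by parameter recovery, so the generator
plants a known partial-correlation network — a connected block of ordinal
symptom items, a block of system-specific chronic-disease cluster counts, and
a small number of positive symptom-disease "bridge" edges — and draws subjects
from the implied Gaussian copula. Symptom severities are discretized onto the
0-6 clinical severity scale with right-skewed margins (the modal response is
"absent"); disease burden per cluster is a Poisson-marginal count; age, sex
and a 3-level education covariate are appended with configurable dependence
on the latent field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrueNetworkSpec",
    "SyntheticCohort",
    "make_true_network",
    "sample_cohort",
    "inject_redundant_pairs",
    "write_cohort",
    "DEFAULT_SEVERITY_CUMPROBS",
]

# cumulative probabilities of severities 0..5 (severity 6 takes the remainder);
# right-skewed so that "absent" is the modal category for every item
DEFAULT_SEVERITY_CUMPROBS = (0.60, 0.75, 0.85, 0.92, 0.96, 0.99)

# covariate defaults for an urban 60+ cohort: mean age ~73, ~63% women,
# education split elementary/high-school/university ~ 15/50/35
DEFAULT_COVARIATES = {
    "age_mean": 73.1,
    "age_sd": 10.4,
    "p_female": 0.63,
    "education_probs": (0.15, 0.50, 0.35),
}


class NetworkConstructionError(RuntimeError):
    """Planted network could not be made positive definite."""


@dataclass
class TrueNetworkSpec:
    """Ground-truth partial-correlation network for a simulated cohort."""

    node_labels: list[str]
    community: dict[str, str]
    partial_corr_true: np.ndarray
    bridge_edges: list[tuple[str, str, float]]
    seed: int
    redundant_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.node_labels)

    def precision(self) -> np.ndarray:
        """Implied precision: unit diagonal, K_ij = -w_ij."""
        K = -self.partial_corr_true.copy()
        np.fill_diagonal(K, 1.0)
        return K

    def covariance(self) -> np.ndarray:
        """Implied standardized covariance (inverse precision, unit diagonal)."""
        Sigma = np.linalg.inv(self.precision())
        d = np.sqrt(np.diag(Sigma))
        return Sigma / np.outer(d, d)

    def symptom_labels(self) -> list[str]:
        return [l for l in self.node_labels if self.community[l] == "symptom"]

    def cluster_labels(self) -> list[str]:
        return [l for l in self.node_labels if self.community[l] == "disease_cluster"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_labels": self.node_labels,
                "community": self.community,
                "partial_corr_true": self.partial_corr_true.tolist(),
                "bridge_edges": [[a, b, w] for a, b, w in self.bridge_edges],
                "redundant_pairs": [list(p) for p in self.redundant_pairs],
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrueNetworkSpec":
        d = json.loads(text)
        return cls(
            node_labels=d["node_labels"],
            community=d["community"],
            partial_corr_true=np.asarray(d["partial_corr_true"], dtype=float),
            bridge_edges=[(a, b, float(w)) for a, b, w in d["bridge_edges"]],
            seed=int(d["seed"]),
            redundant_pairs=[tuple(p) for p in d.get("redundant_pairs", [])],
        )


@dataclass
class SyntheticCohort:
    """Simulated subjects: ordinal ratings, disease counts, covariates, truth."""

    ratings: pd.DataFrame
    burden: pd.DataFrame
    covariates: pd.DataFrame
    truth: TrueNetworkSpec
    latent: pd.DataFrame = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.ratings)

    def frame(self) -> pd.DataFrame:
        """All observed columns in one table (ratings, burden, covariates)."""
        return pd.concat([self.ratings, self.burden, self.covariates], axis=1)


def make_true_network(
    p_symptoms: int,
    p_clusters: int,
    n_bridges: int,
    edge_density: float = 0.2,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.15, 0.35),
    bridge_weight_range: tuple[float, float] = (0.2, 0.3),
    min_eigenvalue: float = 0.05,
    max_contractions: int = 60,
) -> TrueNetworkSpec:
    """Plant a partial-correlation network with a connected symptom block.

    Within-block edges are sampled at ``edge_density`` (the symptom block gets
    a random spanning tree first, so it is always connected); cross-block
    edges are exactly the ``n_bridges`` planted positive bridges. Off-diagonal
    magnitudes are contracted by 0.9 until the implied precision matrix has
    minimum eigenvalue above ``min_eigenvalue``.
    """
    if p_symptoms < 3:
        raise ValueError("p_symptoms must be >= 3")
    if p_clusters < 0:
        raise ValueError("p_clusters must be >= 0")
    if n_bridges > p_symptoms * p_clusters:
        raise ValueError("n_bridges exceeds the number of cross-block pairs")
    rng = np.random.default_rng(seed)
    sympt = [f"sympt_{i + 1:02d}" for i in range(p_symptoms)]
    clus = [f"clus_{i + 1}" for i in range(p_clusters)]
    labels = sympt + clus
    community = {l: "symptom" for l in sympt} | {l: "disease_cluster" for l in clus}
    p = len(labels)
    W = np.zeros((p, p))

    def draw_weight():
        lo, hi = weight_range
        return rng.uniform(lo, hi)

    # symptom block: random spanning tree (random permutation, attach each
    # node to a random predecessor), then extra edges up to the target density
    order = rng.permutation(p_symptoms)
    for k in range(1, p_symptoms):
        a, b = order[k], order[rng.integers(0, k)]
        W[a, b] = W[b, a] = draw_weight()
    for i in range(p_symptoms):
        for j in range(i + 1, p_symptoms):
            if W[i, j] == 0 and rng.random() < edge_density:
                W[i, j] = W[j, i] = draw_weight()
    # disease block: sparse positive edges at the same density
    for i in range(p_symptoms, p):
        for j in range(i + 1, p):
            if rng.random() < edge_density:
                W[i, j] = W[j, i] = draw_weight()
    # bridges: exactly n_bridges cross-block edges, distinct symptom endpoints
    # while possible so bridge-centrality ranks are well defined
    bridges: list[tuple[str, str, float]] = []
    if n_bridges > 0:
        all_pairs = [(i, j) for i in range(p_symptoms) for j in range(p_symptoms, p)]
        chosen: list[tuple[int, int]] = []
        used_sympt: set[int] = set()
        perm = rng.permutation(len(all_pairs))
        for idx in perm:
            i, j = all_pairs[idx]
            if len(chosen) >= n_bridges:
                break
            if i in used_sympt and len(used_sympt) < p_symptoms:
                continue
            chosen.append((i, j))
            used_sympt.add(i)
        for i, j in chosen:
            w = rng.uniform(*bridge_weight_range)
            W[i, j] = W[j, i] = w
            bridges.append((labels[i], labels[j], float(w)))

    np.fill_diagonal(W, 0.0)
    for _ in range(max_contractions):
        K = -W.copy()
        np.fill_diagonal(K, 1.0)
        if np.linalg.eigvalsh(K).min() > min_eigenvalue:
            bridges = [
                (a, b, float(W[labels.index(a), labels.index(b)])) for a, b, _ in bridges
            ]
            P = W.copy()
            np.fill_diagonal(P, 1.0)
            return TrueNetworkSpec(
                node_labels=labels,
                community=community,
                partial_corr_true=P,
                bridge_edges=bridges,
                seed=seed,
            )
        W *= 0.9
    raise NetworkConstructionError(
        f"could not reach min eigenvalue {min_eigenvalue} after "
        f"{max_contractions} contractions (p={p}, density={edge_density})"
    )


def _discretize(z: np.ndarray, cumprobs: tuple[float, ...]) -> np.ndarray:
    """Map standard-normal latents to ordinal 0..len(cumprobs) via thresholds."""
    cuts = stats.norm.ppf(np.asarray(cumprobs))
    return np.searchsorted(cuts, z, side="left").astype(np.int64)


def sample_cohort(
    spec: TrueNetworkSpec,
    n: int,
    seed: int = 0,
    severity_cumprobs: tuple[float, ...] = DEFAULT_SEVERITY_CUMPROBS,
    cluster_mean: float = 0.8,
    covariate_params: dict | None = None,
    covariate_coupling: float = 0.25,
) -> SyntheticCohort:
    """Draw a cohort from the latent Gaussian implied by ``spec``.

    Symptom columns are the latent Gaussians cut at fixed right-skewed
    thresholds; cluster columns map through the Gaussian copula to Poisson
    margins with mean ``cluster_mean``. Age, sex and education are generated
    with mild dependence (``covariate_coupling``) on the first few latent
    nodes, so covariate adjustment has something real to adjust for.
    """
    p = spec.p
    if n < 10 * p:
        raise ValueError(
            f"n={n} too small: downstream estimation assumes subjects greatly "
            f"outnumber the {p} nodes (need n >= {10 * p})"
        )
    rng = np.random.default_rng(seed)
    Sigma = spec.covariance()
    L = np.linalg.cholesky(Sigma)
    Z = rng.standard_normal((n, p)) @ L.T
    sympt = spec.symptom_labels()
    clus = spec.cluster_labels()
    s_idx = [spec.node_labels.index(l) for l in sympt]
    c_idx = [spec.node_labels.index(l) for l in clus]

    ratings = pd.DataFrame(
        _discretize(Z[:, s_idx], severity_cumprobs), columns=sympt
    )
    U = stats.norm.cdf(Z[:, c_idx]) if c_idx else np.empty((n, 0))
    counts = stats.poisson.ppf(U, mu=cluster_mean).astype(np.int64) if c_idx else U
    burden = pd.DataFrame(counts, columns=clus, dtype=np.int64)
    if len(clus):
        burden["total_count"] = burden[clus].sum(axis=1)

    cp = DEFAULT_COVARIATES | (covariate_params or {})
    rho = covariate_coupling
    # age leans on the first disease-cluster latent (older -> more disease),
    # sex and education on the first symptom latents
    age_anchor = Z[:, c_idx[0]] if c_idx else Z[:, s_idx[0]]
    age = cp["age_mean"] + cp["age_sd"] * (
        rho * age_anchor + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    )
    sex_latent = rho * Z[:, s_idx[0]] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    sex = (sex_latent < stats.norm.ppf(cp["p_female"])).astype(np.int64)
    edu_latent = -rho * Z[:, s_idx[1]] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    edu_cuts = stats.norm.ppf(np.cumsum(cp["education_probs"])[:-1])
    education = np.searchsorted(edu_cuts, edu_latent, side="left").astype(np.int64)
    covariates = pd.DataFrame(
        {"cov_age": age, "cov_sex_female": sex, "cov_education": education}
    )
    latent = pd.DataFrame(Z, columns=spec.node_labels)
    return SyntheticCohort(
        ratings=ratings, burden=burden, covariates=covariates, truth=spec, latent=latent
    )


def inject_redundant_pairs(
    cohort: SyntheticCohort,
    k_pairs: int,
    latent_corr: float = 0.95,
    seed: int = 0,
    severity_cumprobs: tuple[float, ...] = DEFAULT_SEVERITY_CUMPROBS,
) -> SyntheticCohort:
    """Append near-duplicate symptom items sharing a latent with existing ones.

    Redundancy is modelled symmetrically: both members of a pair are noisy
    indicators of the *same* underlying latent, each with independent
    discretization noise, calibrated so their latent correlation equals
    ``latent_corr``. The donor column is re-discretized from its noisy
    indicator and the duplicate appended, so the two items' correlation
    patterns with all other nodes coincide in expectation — exactly the
    signature of a redundant item pair. The (donor, duplicate) pairs are
    recorded in the truth metadata as known-redundant ground truth.
    """
    if k_pairs == 0:
        return cohort
    if latent_corr < 0.9:
        raise ValueError("latent_corr must be >= 0.9 for a redundant near-duplicate")
    sympt = cohort.truth.symptom_labels()
    if k_pairs > len(sympt):
        raise ValueError("k_pairs exceeds the number of symptom items")
    rng = np.random.default_rng(seed)
    donors = [sympt[i] for i in rng.choice(len(sympt), size=k_pairs, replace=False)]
    n = cohort.n
    ratings = cohort.ratings.copy()
    latent = cohort.latent.copy()
    pairs = list(cohort.truth.redundant_pairs)
    a = np.sqrt(latent_corr)
    b = np.sqrt(1.0 - latent_corr)
    for donor in donors:
        dup = f"{donor}_dup"
        z = cohort.latent[donor].to_numpy()
        z_a = a * z + b * rng.standard_normal(n)
        z_b = a * z + b * rng.standard_normal(n)
        ratings[donor] = _discretize(z_a, severity_cumprobs)
        ratings[dup] = _discretize(z_b, severity_cumprobs)
        latent[donor] = z_a
        latent[dup] = z_b
        pairs.append((donor, dup))
    # the duplicate columns live only in the ratings panel; the planted network
    # (node_labels, partial_corr_true) keeps describing the base nodes
    truth = TrueNetworkSpec(
        node_labels=list(cohort.truth.node_labels),
        community=dict(cohort.truth.community),
        partial_corr_true=cohort.truth.partial_corr_true,
        bridge_edges=cohort.truth.bridge_edges,
        seed=cohort.truth.seed,
        redundant_pairs=pairs,
    )
    return SyntheticCohort(
        ratings=ratings,
        burden=cohort.burden,
        covariates=cohort.covariates,
        truth=truth,
        latent=latent,
    )


def write_cohort(cohort: SyntheticCohort, path: str | Path) -> tuple[Path, Path]:
    """Write observed columns to CSV plus a sidecar JSON with the truth spec."""
    path = Path(path)
    cohort.frame().to_csv(path, index=False)
    sidecar = path.with_suffix(".truth.json")
    sidecar.write_text(cohort.truth.to_json())
    return path, sidecar
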