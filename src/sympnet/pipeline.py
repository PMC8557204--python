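"""Configuration-driven orchestration of the full network analysis.

The pipeline mirrors the study design: (optional) exclusion cascade →
redundancy detection and averaging merge → three networks estimated
separately — (1) symptoms only, (2) symptoms plus the system-specific disease
cluster counts, (3) symptoms plus the overall disease count — followed by
node metrics, bridge tables, optional covariate-adjusted networks and
case-dropping bootstrap stability. Every artifact is written in an open
format (CSV, JSON, GraphML) and listed in a manifest with content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import adjust, bridge, ggm, metrics, preprocessing, stability

log = logging.getLogger("sympnet")

__all__ = ["PipelineConfig", "run_pipeline", "read_cohort", "write_fit", "write_graphml"]


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs, loadable from YAML."""

    data_path: str
    out_dir: str
    seed: int
    gamma: float = 0.5
    symptom_prefix: str = "sympt_"
    cluster_prefix: str = "clus_"
    covariate_prefix: str = "cov_"
    total_count_column: str = "total_count"
    redundancy: dict = field(
        default_factory=lambda: {"r_min": 0.50, "alpha": 0.05, "prop_max": 0.25}
    )
    bridge_cutoffs: tuple = (0.15, 0.25, 0.35)
    run_adjusted: bool = False
    run_stability: bool = False
    stability_grid: tuple = (0.1, 0.25, 0.5, 0.75)
    stability_replicates: int = 20
    exclusion_flags_path: str | None = None
    exclusion_order: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def read_cohort(
    path: str | Path,
    symptom_prefix: str = "sympt_",
    cluster_prefix: str = "clus_",
    covariate_prefix: str = "cov_",
    total_count_column: str = "total_count",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read a cohort CSV/TSV and split columns by role.

    Symptom columns must hold integers 0-6 (missing allowed); count columns
    must be non-negative integers. Violations are reported with row and
    column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    sympt = [c for c in df.columns if c.startswith(symptom_prefix)]
    clus = [c for c in df.columns if c.startswith(cluster_prefix)]
    if total_count_column in df.columns:
        clus_all = clus + [total_count_column]
    else:
        clus_all = clus
    cov = [c for c in df.columns if c.startswith(covariate_prefix)]
    ratings = df[sympt]
    preprocessing.validate_ratings(ratings)
    for c in clus_all:
        col = df[c]
        bad = col.dropna()
        if ((bad < 0) | (bad != np.round(bad))).any():
            row = int(((bad < 0) | (bad != np.round(bad))).idxmax())
            raise ValueError(f"invalid disease count at row {row}, column {c!r}")
    return ratings, df[clus_all], df[cov]


def write_fit(fit: ggm.GGMFit, stem: Path) -> list[Path]:
    """Serialize a fit as edge-list CSV, JSON and GraphML."""
    paths = []
    edges = fit.edge_list()
    p_csv = stem.with_suffix(".edges.csv")
    edges.to_csv(p_csv, index=False)
    paths.append(p_csv)
    p_json = stem.with_suffix(".fit.json")
    p_json.write_text(fit.to_json())
    paths.append(p_json)
    paths.append(write_graphml(fit, stem.with_suffix(".graphml")))
    return paths


def write_graphml(fit: ggm.GGMFit, path: Path) -> Path:
    labels = fit.labels or [str(i) for i in range(fit.p)]
    G = nx.Graph()
    G.add_nodes_from(labels)
    for i, j in zip(*np.triu_indices(fit.p, 1)):
        if fit.structure[i, j]:
            G.add_edge(labels[i], labels[j], weight=float(fit.weights[i, j]))
    nx.write_graphml(G, path)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _estimate(panel: pd.DataFrame, gamma: float) -> ggm.GGMFit:
    R = ggm.spearman_corr(panel)
    return ggm.model_search(R, gamma=gamma)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the artifact manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        ver = _pkg_version("sympnet")
    except Exception:  # editable/unbuilt tree
        ver = "unknown"
    log.info(
        "pipeline start: seed=%s gamma=%s redundancy=%s version=%s",
        config.seed, config.gamma, config.redundancy, ver,
    )
    artifacts: list[Path] = []
    ratings, burden, covars = read_cohort(
        config.data_path,
        config.symptom_prefix,
        config.cluster_prefix,
        config.covariate_prefix,
        config.total_count_column,
    )

    # --- exclusion cascade (optional)
    if config.exclusion_flags_path:
        flags = pd.read_csv(config.exclusion_flags_path)
        kept, report = preprocessing.apply_exclusions(flags, config.exclusion_order)
        keep_idx = kept[kept].index
        ratings, burden, covars = (
            ratings.loc[keep_idx],
            burden.loc[keep_idx],
            covars.loc[keep_idx],
        )
        p = out / "exclusion_report.csv"
        report.to_frame().to_csv(p, index=False)
        artifacts.append(p)
        log.info("exclusions: %d -> %d subjects", report.n_initial, report.n_final)

    # --- redundancy detection and averaging merge
    red = preprocessing.detect_redundant_pairs(ratings, **config.redundancy)
    merged = preprocessing.merge_items(ratings, red.merge_map)
    p = out / "redundancy_report.csv"
    red.pairs.to_csv(p, index=False)
    artifacts.append(p)
    p = out / "merged_ratings.csv"
    merged.to_csv(p, index=False)
    artifacts.append(p)
    log.info(
        "redundancy: %d pairs merged, %d -> %d items",
        len(red.flagged), ratings.shape[1], merged.shape[1],
    )

    cluster_cols = [c for c in burden.columns if c != config.total_count_column]
    networks: dict[str, tuple[ggm.GGMFit, pd.DataFrame]] = {}

    # --- network 1: symptoms only
    fit1 = _estimate(merged, config.gamma)
    networks["net1_symptoms"] = (fit1, merged)

    # --- network 2: symptoms + disease clusters; network 3: symptoms + total count
    if cluster_cols:
        panel2 = pd.concat([merged, burden[cluster_cols]], axis=1)
        networks["net2_clusters"] = (_estimate(panel2, config.gamma), panel2)
    else:
        log.info("no cluster columns found; skipping network 2 (clusters)")
    if config.total_count_column in burden.columns:
        panel3 = pd.concat([merged, burden[[config.total_count_column]]], axis=1)
        networks["net3_total_burden"] = (_estimate(panel3, config.gamma), panel3)
    else:
        log.info("no total-count column found; skipping network 3 (overall burden)")

    summary: dict[str, dict] = {}
    for name, (fit, panel) in networks.items():
        artifacts += write_fit(fit, out / name)
        tbl = metrics.node_metrics_table(
            fit.weights, data=panel, structure=fit.structure, labels=fit.labels
        )
        p = out / f"{name}.metrics.csv"
        tbl.to_csv(p, index_label="node")
        artifacts.append(p)
        layout = metrics.fr_layout(fit.weights, seed=config.seed)
        p = out / f"{name}.layout.csv"
        pd.DataFrame(
            [(fit.labels[i], xy[0], xy[1]) for i, xy in layout.items()],
            columns=["node", "x", "y"],
        ).to_csv(p, index=False)
        artifacts.append(p)
        desc = {
            "n": fit.n,
            "p": fit.p,
            "edges": fit.n_edges,
            "density": metrics.density(fit.structure),
            "ebic": fit.ebic,
            "gamma": fit.gamma,
        }
        try:
            desc["omega"] = metrics.small_world_omega(
                fit.structure, n_ref=50, seed=config.seed
            )
        except ValueError as exc:
            log.info("omega unavailable for %s: %s", name, exc)
        summary[name] = desc
        # bridge tables for the mixed symptom/disease networks
        if name != "net1_symptoms":
            comm = {
                l: ("symptom" if l in merged.columns else "somatic") for l in fit.labels
            }
            bt = bridge.bridge_expected_influence(fit.weights, comm, fit.labels)
            p = out / f"{name}.bridge_ei.csv"
            bt.to_csv(p, index_label="node")
            artifacts.append(p)
            cl = bridge.network_cross_loadings(
                fit.weights, comm, fit.labels, cutoffs=tuple(config.bridge_cutoffs)
            )
            p = out / f"{name}.cross_loadings.csv"
            cl.to_csv(p, index=False)
            artifacts.append(p)
            er = bridge.bridge_edge_report(fit.weights, comm, fit.labels)
            p = out / f"{name}.bridge_edges.csv"
            er.to_csv(p, index=False)
            artifacts.append(p)

    # --- covariate-adjusted network (optional, symptoms + clusters + covariates)
    if config.run_adjusted and "net2_clusters" in networks and len(covars.columns):
        fit2, panel2 = networks["net2_clusters"]
        mixed = pd.concat([panel2, covars], axis=1)
        types = {c: "ordinal" for c in merged.columns}
        types |= {c: "count" for c in cluster_cols}
        for c in covars.columns:
            types[c] = "binary" if mixed[c].nunique() == 2 else "continuous"
        mgm = adjust.fit_mgm(
            adjust.MixedVariableTable(mixed, types), gamma=config.gamma, seed=config.seed
        )
        comm = {l: ("symptom" if l in merged.columns else "somatic") for l in fit2.labels}
        crude_edges = bridge.bridge_edge_report(fit2.weights, comm, fit2.labels)
        sub = [mgm.labels.index(l) for l in fit2.labels]
        adj_edges = bridge.bridge_edge_report(
            mgm.weights[np.ix_(sub, sub)], comm, fit2.labels
        )
        pres = adjust.bridge_preservation(crude_edges, adj_edges)
        p = out / "bridge_preservation.csv"
        pres.to_csv(p, index=False)
        artifacts.append(p)
        p = out / "adjusted_network.edges.csv"
        pd.DataFrame(
            [
                (mgm.labels[i], mgm.labels[j], mgm.weights[i, j])
                for i, j in zip(*np.triu_indices(len(mgm.labels), 1))
                if mgm.weights[i, j] != 0
            ],
            columns=["node_i", "node_j", "weight"],
        ).to_csv(p, index=False)
        artifacts.append(p)

    # --- case-dropping bootstrap stability (optional, on the symptom network)
    if config.run_stability:
        def centrality(df: pd.DataFrame) -> dict:
            fit = _estimate(df, config.gamma)
            raw, _ = metrics.expected_influence(fit.weights)
            return {"expected_influence": raw}

        res = stability.case_dropping_bootstrap(
            merged,
            centrality,
            drop_grid=tuple(config.stability_grid),
            n_replicates=config.stability_replicates,
            seed=config.seed,
        )
        p = out / "stability_records.csv"
        res.records.to_csv(p, index=False)
        artifacts.append(p)
        cs = stability.cs_coefficient(res)
        p = out / "stability_summary.json"
        p.write_text(json.dumps({"cs_coefficient": cs, "n_failures": res.n_failures}))
        artifacts.append(p)
        summary["stability_cs"] = cs

    p = out / "network_summary.json"
    p.write_text(json.dumps(summary, indent=1))
    artifacts.append(p)
    manifest = {
        "version": ver,
        "seed": config.seed,
        "gamma": config.gamma,
        "files": {a.name: _sha256(a) for a in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline done: %d artifacts in %s", len(artifacts), out)
    return manifest
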