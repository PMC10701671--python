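"""End-to-end orchestration: QC -> diversity -> network -> summaries.

``run_pipeline`` executes the stages in their canonical order
(decontaminate, drop singletons, rarefy, normalise, diversity, global
network, per-group networks, cluster summaries), writes every artifact
under the output directory, and records a machine-readable manifest with
package versions, parameters, the seed, and input checksums. All
randomness flows from the single configured seed through per-stage derived
seeds, so a repeated run is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cluster_summary, diversity, network, preprocess

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "assignment_from_membership"]


@dataclass
class RunConfig:
    """Inputs, parameters, and output location for a full pipeline run."""

    feature_table: str
    out_dir: str
    metadata: str | None = None
    batch_map: str | None = None
    taxonomy: str | None = None
    depth: int = 9957
    min_obs: int = 5
    rho_min: float = 0.6
    p_max: float = 0.05
    fold: float = 10.0
    pseudo: str | float = "auto"
    seed: int = 0
    group_by: str | None = None
    singleton_mode: str = "total"
    control_norm: str = "controls"

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.min_obs < 1:
            raise ValueError(f"min_obs must be >= 1, got {self.min_obs}")
        if not 0 <= self.rho_min < 1:
            raise ValueError(f"rho_min must be in [0, 1), got {self.rho_min}")
        if not 0 < self.p_max <= 1:
            raise ValueError(f"p_max must be in (0, 1], got {self.p_max}")
        if self.fold <= 0:
            raise ValueError(f"fold must be positive, got {self.fold}")


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % 2**31)


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _network_stage(
    rel: pd.DataFrame,
    meta: pd.DataFrame | None,
    config: RunConfig,
    out_dir: Path,
    taxonomy: dict | None,
) -> dict:
    """Build, partition, and export one network; returns summary counts."""
    scaled = None
    if meta is not None:
        numeric = meta.loc[[s for s in rel.columns if s in meta.index]]
        scaled = preprocess.scale_metadata(numeric)
    nodes = network.assemble_node_table(rel, scaled, min_shared=config.min_obs)
    net = network.build_network(
        nodes, min_obs=config.min_obs, rho_min=config.rho_min, p_max=config.p_max
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    if net.number_of_edges() == 0:
        (out_dir / "edge-list.csv").write_text("u,v,rho,p,n_obs,cluster_u,cluster_v\n")
        return {"nodes": 0, "edges": 0, "clusters": 0}
    assign = network.girvan_newman_partition(net)
    network.edge_list_frame(net, assign).to_csv(out_dir / "edge-list.csv", index=False)
    network.membership_frame(net, assign).to_csv(out_dir / "cluster-membership.csv", index=False)
    network.write_graphml(net, out_dir / "network.graphml", assign=assign, taxonomy=taxonomy)
    abund = cluster_summary.cluster_abundance(rel, assign)
    abund.to_csv(out_dir / "cluster-abundance.tsv", sep="\t")
    prev = cluster_summary.cluster_prevalence(rel, assign)
    prev.rename_axis("cluster").to_csv(out_dir / "cluster-prevalence.tsv", sep="\t")
    return {
        "nodes": net.number_of_nodes(),
        "edges": net.number_of_edges(),
        "clusters": assign.n_clusters,
        "modularity": assign.modularity,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {
            "taxonet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in {"feature_table", "out_dir"}
        },
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "warnings": [],
    }

    table = preprocess.read_feature_table(config.feature_table)
    manifest["inputs"]["feature_table"] = _sha256(config.feature_table)
    meta = None
    if config.metadata:
        meta = preprocess.read_metadata(config.metadata)
        manifest["inputs"]["metadata"] = _sha256(config.metadata)
    taxonomy = None
    if config.taxonomy:
        taxonomy = preprocess.read_taxonomy(config.taxonomy)
        manifest["inputs"]["taxonomy"] = _sha256(config.taxonomy)

    if config.batch_map:
        batch_map = preprocess.read_batch_map(config.batch_map)
        manifest["inputs"]["batch_map"] = _sha256(config.batch_map)
        table, removed = preprocess.remove_contaminants(
            table, batch_map, fold=config.fold, control_norm=config.control_norm
        )
        (out_dir / "removed-contaminants.txt").write_text("".join(f"{f}\n" for f in removed))
        manifest["stages"]["decontaminate"] = {"removed_features": len(removed)}

    table = preprocess.remove_singletons(table, mode=config.singleton_mode)
    manifest["stages"]["singletons"] = {"features_after": int(table.shape[0])}

    table = preprocess.rarefy(table, config.depth, seed=_stage_seed(config.seed, 1))
    preprocess.write_feature_table(table, out_dir / "rarefied-table.tsv")
    manifest["stages"]["rarefy"] = {
        "depth": config.depth,
        "samples_after": int(table.shape[1]),
    }

    rel = preprocess.to_relative_abundance(table)

    # diversity exports
    diversity.alpha_diversity(table).rename_axis("sample-id").to_csv(
        out_dir / "shannon.tsv", sep="\t"
    )
    if rel.shape[1] >= 2:
        diversity.bray_curtis(rel).write(str(out_dir / "bray-curtis.tsv"))
        logged = preprocess.log10_compositions(rel, pseudo=config.pseudo)
        manhattan = diversity.manhattan(logged)
        manhattan.write(str(out_dir / "manhattan-log10.tsv"))
        tree = diversity.hierarchical_cluster(manhattan, linkage="complete")
        (out_dir / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    diversity.presence_absence(table).to_csv(out_dir / "presence-absence.tsv", sep="\t")

    manifest["stages"]["global_network"] = _network_stage(
        rel, meta, config, out_dir / "network", taxonomy
    )

    if config.group_by:
        if meta is None or config.group_by not in meta.columns:
            raise ValueError(f"unknown grouping variable {config.group_by!r}")
        groups: dict = {}
        for value in sorted(meta[config.group_by].dropna().astype(str).unique()):
            members = meta.index[meta[config.group_by].astype(str) == value]
            subset = [s for s in rel.columns if s in set(members)]
            sub_rel = rel[subset]
            try:
                groups[value] = _network_stage(
                    sub_rel,
                    meta.drop(columns=[config.group_by]),
                    config,
                    out_dir / "networks" / value,
                    taxonomy,
                )
            except ValueError as exc:
                manifest["warnings"].append(f"group {value!r}: {exc}")
        manifest["stages"]["group_networks"] = groups

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def assignment_from_membership(frame: pd.DataFrame) -> network.ClusterAssignment:
    """Rebuild a ClusterAssignment from an exported membership table."""
    labels = dict(zip(frame["node_id"], frame["cluster"].astype(int)))
    kinds = dict(zip(frame["node_id"], frame["kind"]))
    return network.ClusterAssignment(labels=labels, kinds=kinds, modularity=float("nan"))
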