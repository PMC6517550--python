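"""Plain-text readers and writers for all pipeline artifacts.

Formats: counts TSV (first column gene id, one column per sample), sample
metadata TSV, growth-curve TSV (time_h, cdw_gL), regulatory-network TSV
(regulator TAB target, ``#`` comments), GMT gene sets, ground-truth JSON,
dissimilarity-matrix TSV and Newick dendrograms.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from growthmodulon.kinetics import GrowthSeries
from growthmodulon.simulate import GroundTruth

__all__ = [
    "read_counts", "write_counts",
    "read_sample_meta", "write_sample_meta",
    "read_growth_curve", "write_growth_curve",
    "read_network", "write_network",
    "read_gmt", "write_gmt",
    "read_ground_truth", "write_ground_truth",
    "linkage_to_newick",
]


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "replicate", "mu"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")
    return meta


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_growth_curve(path, viability: float = 100.0,
                      condition: str = "") -> GrowthSeries:
    df = pd.read_csv(path, sep="\t")
    return GrowthSeries(
        time=df["time_h"].to_numpy(),
        cdw=df["cdw_gL"].to_numpy(),
        viability_at_inoculation=viability,
        condition=condition,
    )


def write_growth_curve(series: GrowthSeries, path) -> None:
    pd.DataFrame({"time_h": series.time, "cdw_gL": series.cdw}).to_csv(
        path, sep="\t", index=False
    )


def read_network(path) -> pd.DataFrame:
    edges = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["regulator", "target"],
        dtype=str, skip_blank_lines=True,
    )
    if edges.duplicated().any():
        raise ValueError("network edge list contains duplicate edges")
    return edges


def write_network(edges: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# regulator\ttarget\n")
        edges.to_csv(fh, sep="\t", index=False, header=False)


def read_gmt(path) -> dict:
    """Read a GMT file: ``set name TAB description TAB member genes...``."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = fields[2:]
    return sets


def write_gmt(sets: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "modulon_genes": sorted(truth.modulon_genes),
        "cluster_of_gene": {g: int(c) for g, c in truth.cluster_of_gene.items()},
        "private_deg_genes": {
            c: sorted(g) for c, g in truth.private_deg_genes.items()
        },
        "enriched_regulators": sorted(truth.enriched_regulators),
        "mean_profile": [
            {"gene": g, "condition": c, "mu": m, "log2fc": v}
            for (g, c, m), v in truth.mean_profile.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        modulon_genes=set(payload["modulon_genes"]),
        cluster_of_gene={
            g: int(c) for g, c in payload["cluster_of_gene"].items()
        },
        private_deg_genes={
            c: set(g) for c, g in payload["private_deg_genes"].items()
        },
        enriched_regulators=set(payload["enriched_regulators"]),
        mean_profile={
            (e["gene"], e["condition"], e["mu"]): e["log2fc"]
            for e in payload["mean_profile"]
        },
    )


def linkage_to_newick(z: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    labels = list(labels)
    if len(labels) == 1:
        return f"{labels[0]};"
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"
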