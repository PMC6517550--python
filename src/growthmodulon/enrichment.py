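"""Regulon and gene-set over-representation within the modulon.

Each regulator's regulon (its target set in a curated regulatory network) is
tested for over-representation in the modulon with an upper-tail
hypergeometric test: with a gene universe of size N (all genes retained in
the count matrix), a regulon of size K within that universe, and a modulon
of size n, the p-value is P(X >= k) for the observed overlap k.  BH controls
the FDR across all tested sets.  Per significant regulon, the overlap is
broken down by expression-profile cluster (the shape of the study's
regulon-summary table), and the significant regulator -> modulon-target
subnetwork can be exported as a SIF-style edge list with node attributes.

The same machinery serves generic gene-set collections (GMT files, e.g.
pathways), conventionally at a stricter level (alpha = 0.025).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from growthmodulon.de import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_upper_tail",
    "enrich_sets",
    "cluster_breakdown",
    "regulons_from_edges",
    "export_network",
    "read_sif",
]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` genes of a set of size ``K`` were found among ``n`` draws from a
    universe of ``N``.  ``P(X >= 0) = 1`` exactly.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError("set size and draw size cannot exceed the universe")
    if k > min(K, n):
        raise ValueError("overlap k cannot exceed min(K, n)")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def regulons_from_edges(edges: pd.DataFrame) -> dict:
    """Group a regulator -> target edge list into ``{regulator: target set}``."""
    if not {"regulator", "target"} <= set(edges.columns):
        raise ValueError("edge list needs 'regulator' and 'target' columns")
    out: dict = {}
    for reg, sub in edges.groupby("regulator"):
        out[str(reg)] = set(sub["target"].astype(str))
    return out


def cluster_breakdown(overlap_genes, cluster_of_gene: dict, k: int = 4) -> tuple:
    """Counts of overlap genes per profile cluster 1..k (summing to the
    overlap size).  Every overlap gene must carry a cluster label."""
    counts = [0] * k
    for g in overlap_genes:
        if g not in cluster_of_gene:
            raise ValueError(f"gene {g!r} has no cluster label")
        c = cluster_of_gene[g]
        if not 1 <= c <= k:
            raise ValueError(f"cluster label {c} of gene {g!r} outside 1..{k}")
        counts[c - 1] += 1
    return tuple(counts)


def enrich_sets(
    modulon,
    sets: dict,
    universe,
    alpha: float = 0.05,
    *,
    min_set_size: int = 2,
    cluster_of_gene: dict | None = None,
    n_profile_clusters: int = 4,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets within the modulon.

    Parameters
    ----------
    modulon : gene set drawn from ``universe``.
    sets : mapping set id (regulator or pathway) -> member gene collection;
        members are intersected with the universe before counting, and sets
        with fewer than ``min_set_size`` members in the universe are skipped.
    universe : the gene background (all genes retained in the count matrix).
    alpha : BH-adjusted significance level.
    cluster_of_gene : optional modulon-gene -> cluster map; when given, the
        overlap of each set is broken down into ``cluster_1..k`` columns.

    Returns
    -------
    DataFrame sorted by adjusted p with columns ``set_id, k, K, n, N,
    p_value, p_adjusted, significant`` (+ cluster columns).
    """
    universe = set(universe)
    modulon = set(modulon)
    if not universe:
        raise ValueError("empty gene universe")
    if not sets:
        raise ValueError("empty gene-set collection")
    if not modulon <= universe:
        missing = sorted(modulon - universe)[:5]
        raise ValueError(
            f"modulon genes missing from the universe, e.g. {missing}"
        )
    N = len(universe)
    n = len(modulon)
    rows = []
    for set_id, members in sets.items():
        members = set(members)
        unknown = members - universe
        if unknown:
            logger.info(
                "set %s: %d members outside the universe ignored",
                set_id, len(unknown),
            )
        members &= universe
        K = len(members)
        if K < min_set_size:
            continue
        overlap = members & modulon
        k = len(overlap)
        row = {
            "set_id": set_id,
            "k": k,
            "K": K,
            "n": n,
            "N": N,
            "p_value": hypergeom_upper_tail(k, K, n, N),
        }
        if cluster_of_gene is not None:
            counts = cluster_breakdown(
                overlap, cluster_of_gene, k=n_profile_clusters
            )
            for c, v in enumerate(counts, start=1):
                row[f"cluster_{c}"] = v
        row["_overlap"] = sorted(overlap)
        rows.append(row)
    if not rows:
        raise ValueError(
            f"no set has >= {min_set_size} members in the universe"
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    out = out.sort_values(
        ["p_adjusted", "p_value", "set_id"], kind="stable"
    ).reset_index(drop=True)
    out.attrs["alpha"] = alpha
    out.attrs["universe_size"] = N
    return out


def export_network(
    rows: pd.DataFrame,
    network: pd.DataFrame,
    cluster_of_gene: dict,
    edges_path,
    nodes_path,
) -> None:
    """Write the significant-regulator subnetwork.

    ``edges_path`` receives a SIF-style TSV (``regulator  regulates  target``)
    restricted to significant regulators and their modulon targets;
    ``nodes_path`` a node-attribute TSV (``node  type  cluster``) where
    regulators have an empty cluster field.  Files always include a header so
    an empty result still round-trips.
    """
    sig = rows.loc[rows["significant"], ["set_id", "_overlap"]] \
        if len(rows) else pd.DataFrame(columns=["set_id", "_overlap"])
    edge_records = []
    node_records = []
    seen_targets = set()
    regulons = regulons_from_edges(network) if len(sig) else {}
    for _, r in sig.iterrows():
        reg = r["set_id"]
        targets = sorted(set(r["_overlap"]) & regulons.get(reg, set()))
        node_records.append({"node": reg, "type": "regulator", "cluster": ""})
        for t in targets:
            edge_records.append(
                {"source": reg, "interaction": "regulates", "target": t}
            )
            seen_targets.add(t)
    for t in sorted(seen_targets):
        node_records.append(
            {"node": t, "type": "gene", "cluster": cluster_of_gene.get(t, "")}
        )
    pd.DataFrame(
        edge_records, columns=["source", "interaction", "target"]
    ).to_csv(edges_path, sep="\t", index=False)
    pd.DataFrame(
        node_records, columns=["node", "type", "cluster"]
    ).to_csv(nodes_path, sep="\t", index=False)


def read_sif(edges_path) -> pd.DataFrame:
    """Read a SIF-style edge TSV written by :func:`export_network`."""
    return pd.read_csv(edges_path, sep="\t", dtype=str)
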