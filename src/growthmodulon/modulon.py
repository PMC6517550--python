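"""Growth-modulon identification and expression-profile clustering.

The modulon is built in two steps.  First, the per-condition DEG sets are
intersected: a gene must respond to the growth rate after every pre-culture
condition.  Second, the fitted cubic log2FC profiles of each intersection
gene are compared across conditions on a common rate grid; the gene joins
the modulon only when the minimum pairwise Pearson correlation of its
condition profiles reaches a similarity threshold (default 0.7), i.e. its
response shape is independent of the pre-culture.

Modulon genes are then partitioned into expression-profile clusters by
agglomerative (Ward) clustering of their condition-averaged fitted profiles
under the correlation distance (1 - Pearson), cut at k = 4 (a
concatenated-profile mode is available).  Cluster labels are given
fixed semantics (1 = steady rise, 2 = late sharp rise, 3 = rise then fall on
the last interval, 4 = steady fall) by matching cluster mean profiles to the
four canonical shape templates, so labels are comparable across runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin

from growthmodulon.de import evaluate_log2fc
from growthmodulon.simulate import make_profile_templates

logger = logging.getLogger(__name__)

__all__ = [
    "ModulonResult",
    "ProfileClusterer",
    "intersect_degs",
    "profile_similarity",
    "identify_modulon",
    "cluster_profiles",
]

#: fitted profiles spanning less than this log2 range count as flat; their
#: Pearson correlation with anything is numerical noise
FLAT_PROFILE_EPS = 0.1


@dataclass
class ModulonResult:
    """Outcome of modulon identification.

    ``similarity_score`` maps every intersection gene to its minimum pairwise
    cross-condition profile correlation (NaN for flat-profile exclusions).
    ``cluster_of_gene`` and ``mean_cluster_profiles`` are filled by
    :func:`cluster_profiles`.
    """

    intersection_genes: set
    modulon_genes: set
    similarity_score: dict
    similarity_threshold: float
    overlap_fractions: dict
    grid: np.ndarray
    cluster_of_gene: dict | None = None
    mean_cluster_profiles: pd.DataFrame | None = None


def intersect_degs(deg_sets):
    """Intersect per-condition DEG sets.

    Parameters
    ----------
    deg_sets : sequence of :class:`~growthmodulon.de.DEGSet` (or mapping
        condition -> gene set), at least two conditions.

    Returns
    -------
    (shared, fractions) : the exact set intersection and, per condition, the
    fraction of that condition's DEGs contained in the intersection.
    """
    if isinstance(deg_sets, dict):
        items = [(c, set(g)) for c, g in deg_sets.items()]
    else:
        items = [(d.condition, set(d.genes)) for d in deg_sets]
    if len(items) < 2:
        raise ValueError("need DEG sets from at least two conditions")
    shared = set.intersection(*(g for _, g in items))
    fractions = {
        c: (len(shared) / len(g) if g else float("nan")) for c, g in items
    }
    return shared, fractions


def _profiles_on_grid(fits_by_condition, gene, grid, degree):
    """Per-condition fitted log2FC vectors of one gene on a common grid."""
    out = {}
    for cond, table in fits_by_condition.items():
        if gene not in table.index:
            return None
        beta = table.loc[
            gene, [f"beta{k}" for k in range(degree + 1)]
        ].to_numpy(dtype=float)
        out[cond] = evaluate_log2fc(beta, grid, table.attrs["reference_mu"])
    return out


def profile_similarity(profiles) -> float:
    """Minimum pairwise Pearson correlation between condition profiles.

    ``profiles`` maps condition -> log2FC vector on a common rate grid.
    Profiles whose range is below :data:`FLAT_PROFILE_EPS` in any condition
    yield NaN (correlations of near-constant vectors are noise; such genes
    are excluded from the modulon and logged by the caller).
    """
    vecs = [np.asarray(v, dtype=float) for v in profiles.values()]
    if len(vecs) < 2:
        raise ValueError("need profiles from at least two conditions")
    if any(np.ptp(v) < FLAT_PROFILE_EPS for v in vecs):
        return float("nan")
    score = 1.0
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            r = np.corrcoef(vecs[i], vecs[j])[0, 1]
            score = min(score, r)
    return float(score)


def identify_modulon(
    deg_sets,
    fits_by_condition: dict,
    similarity_threshold: float = 0.7,
    *,
    grid=None,
) -> ModulonResult:
    """Identify the growth modulon.

    Parameters
    ----------
    deg_sets : per-condition DEG sets (see :func:`intersect_degs`).
    fits_by_condition : mapping condition -> fit table from
        :func:`~growthmodulon.de.fit_rate_course`.
    similarity_threshold : minimum cross-condition profile correlation in
        (-1, 1]; -1 disables the filter (modulon = intersection).
    grid : common rate grid for profile comparison; defaults to the
        intersection of the conditions' grids.

    Returns
    -------
    ModulonResult with cluster fields unset.
    """
    if not -1.0 <= similarity_threshold <= 1.0:
        raise ValueError("similarity_threshold must be in [-1, 1]")
    shared, fractions = intersect_degs(deg_sets)
    if not shared:
        warnings.warn("empty DEG intersection: empty modulon", stacklevel=2)
    if grid is None:
        grids = [set(t.attrs["mu_grid"]) for t in fits_by_condition.values()]
        grid = sorted(set.intersection(*grids))
    grid = np.asarray(grid, dtype=float)
    degree = next(iter(fits_by_condition.values())).attrs["degree"]

    scores = {}
    modulon = set()
    n_flat = n_missing = 0
    for gene in sorted(shared):
        profiles = _profiles_on_grid(fits_by_condition, gene, grid, degree)
        if profiles is None:
            n_missing += 1
            logger.info("gene %s lacks a fit in some condition; excluded", gene)
            continue
        score = profile_similarity(profiles)
        scores[gene] = score
        if np.isnan(score):
            n_flat += 1
        elif score >= similarity_threshold:
            modulon.add(gene)
    if n_flat:
        logger.info("%d intersection genes excluded as flat-profile", n_flat)
    return ModulonResult(
        intersection_genes=shared,
        modulon_genes=modulon,
        similarity_score=scores,
        similarity_threshold=similarity_threshold,
        overlap_fractions=fractions,
        grid=grid,
    )


class ProfileClusterer(ClusterMixin, BaseEstimator):
    """Agglomerative clustering of expression profiles, correlation distance.

    ``fit(X)`` takes one row per gene (a concatenated or single profile
    vector); distance is 1 - Pearson correlation between rows, linkage is
    Ward by default, and the tree is cut into ``n_clusters`` flat clusters.  ``labels_`` are 1-based.
    """

    def __init__(self, n_clusters: int = 4, linkage: str = "ward"):
        self.n_clusters = n_clusters
        self.linkage = linkage

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (genes x profile points)")
        if self.n_clusters > X.shape[0]:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds the number of "
                f"profiles ({X.shape[0]})"
            )
        d = pdist(X, metric="correlation")
        d = np.maximum(d, 0.0)  # guard tiny negative rounding
        z = hierarchy.linkage(d, method=self.linkage)
        self.linkage_ = z
        self.labels_ = hierarchy.fcluster(z, t=self.n_clusters,
                                          criterion="maxclust")
        return self


def _relabel_by_shape(labels, gene_profiles, grid, k):
    """Renumber flat-cluster labels to canonical shape semantics.

    For k = 4, cluster means on the common grid are matched one-to-one to the
    four canonical templates by maximal Pearson correlation (Hungarian
    assignment).  For other k, clusters are ordered by descending fitted
    linear slope of their mean profile.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    means = {
        c: gene_profiles[labels == c].mean(axis=0) for c in uniq
    }
    if k == 4 and len(uniq) == 4 and len(grid) >= 3:
        templates = make_profile_templates(grid, amplitude_log2=1.0)
        corr = np.zeros((4, 4))
        for i, c in enumerate(uniq):
            for j, t in enumerate((1, 2, 3, 4)):
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(means[c], templates[t])[0, 1]
                corr[i, j] = 0.0 if np.isnan(r) else r
        rows, cols = linear_sum_assignment(-corr)
        mapping = {uniq[i]: j + 1 for i, j in zip(rows, cols)}
    else:
        x = np.asarray(grid, dtype=float)
        xc = x - x.mean()
        slopes = {
            c: float(xc @ (m - m.mean()) / (xc @ xc)) for c, m in means.items()
        }
        order = sorted(uniq, key=lambda c: -slopes[c])
        mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in labels])


def cluster_profiles(
    result: ModulonResult,
    fits_by_condition: dict,
    k: int = 4,
    *,
    linkage: str = "ward",
    profile: str = "mean",
) -> ModulonResult:
    """Partition the modulon into k expression-profile clusters (in place).

    Per gene, the fitted log2FC profiles of the conditions (each evaluated on
    the common grid) are combined — by default averaged across conditions
    (modulon genes share their shape across conditions by construction of
    the similarity filter, and averaging suppresses per-condition noise;
    this is also the quantity the cluster summary reports), with
    ``profile="concatenated"`` keeping the per-condition chunks side by
    side.  Genes are clustered under the correlation distance with the given
    linkage and the tree is cut at k.  Labels follow the canonical shape
    semantics (see module docstring) and ``mean_cluster_profiles`` holds
    per-cluster mean log2FC on the common grid, averaged over conditions.
    """
    genes = sorted(result.modulon_genes)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the modulon size ({len(genes)})")
    if profile not in ("mean", "concatenated"):
        raise ValueError(f"unknown profile mode {profile!r}")
    grid = result.grid
    degree = next(iter(fits_by_condition.values())).attrs["degree"]
    conditions = list(fits_by_condition)

    chunks = []
    for gene in genes:
        profiles = _profiles_on_grid(fits_by_condition, gene, grid, degree)
        chunks.append(np.concatenate([profiles[c] for c in conditions]))
    concat = np.asarray(chunks)
    n_grid = grid.size
    per_cond = concat.reshape(len(genes), len(conditions), n_grid)
    avg_profiles = per_cond.mean(axis=1)

    features = avg_profiles if profile == "mean" else concat
    clusterer = ProfileClusterer(n_clusters=k, linkage=linkage).fit(features)
    labels = _relabel_by_shape(clusterer.labels_, avg_profiles, grid, k)

    result.cluster_of_gene = dict(zip(genes, (int(c) for c in labels)))
    rows = {}
    for c in sorted(set(labels.tolist())):
        rows[c] = avg_profiles[labels == c].mean(axis=0)
    result.mean_cluster_profiles = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"{g:g}" for g in grid]
    ).rename_axis("cluster")
    return result
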