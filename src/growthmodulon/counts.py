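"""Count-matrix handling: RLE size factors, Poisson dissimilarity, clustering.

Count matrices are pandas DataFrames with genes as rows and samples as
columns (the layout of the on-disk TSVs).  The scikit-learn style estimators
(:class:`RLENormalizer`, :class:`PoissonSampleClusterer`) follow the sklearn
convention instead — rows are samples, columns are genes — so they compose
with pipelines; the module-level functions are thin wrappers operating on the
genes x samples layout.

Normalization is relative log expression (RLE, median-of-ratios): the size
factor of a sample is the median, over genes expressed in every sample, of
the ratio of its count to the gene's geometric mean across samples.

The sample dissimilarity is the deviance of a Poisson log-linear model: for
two samples with size factors s_i, s_j, the null of a shared relative
abundance profile predicts ``m_gi = s_i (x_gi + x_gj) / (s_i + s_j)`` and the
distance sums per-gene deviance residual contributions of both samples.  It
is zero exactly when the two columns are proportional with ratio s_i/s_j.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "rle_size_factors",
    "poisson_dissimilarity",
    "cluster_samples",
    "drop_all_zero_genes",
    "RLENormalizer",
    "PoissonSampleClusterer",
]


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples count matrix (non-negative, unique ids)."""
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(counts)
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("gene and sample identifiers must be unique")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return counts


def drop_all_zero_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero counts in every sample (they carry no signal
    and break geometric means)."""
    keep = counts.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d all-zero genes", n_dropped)
    return counts.loc[keep]


def rle_size_factors(counts: pd.DataFrame) -> pd.Series:
    """RLE (median-of-ratios) size factors, one positive scalar per sample.

    The reference set is the genes with a positive count in *all* samples.
    """
    counts = validate_counts(counts)
    x = counts.to_numpy(dtype=float)
    ref = (x > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has positive counts in every sample; RLE needs a "
            "non-empty reference set (filter samples or use deeper libraries)"
        )
    logx = np.log(x[ref])
    log_geomean = logx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logx - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _poisson_halfdev(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Per-entry Poisson deviance contribution x*log(x/m) - (x - m), 0log0=0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / m), 0.0)
    return term - (x - m)


def poisson_dissimilarity(
    counts: pd.DataFrame,
    size_factors: pd.Series | None = None,
    *,
    transform: str | None = None,
) -> pd.DataFrame:
    """Poisson-deviance dissimilarity matrix between samples.

    Parameters
    ----------
    counts : genes x samples DataFrame.
    size_factors : per-sample factors; computed by RLE if omitted.
    transform : None or "sqrt"
        Optional square-root variance stabilization applied to counts (and
        the square root to the factors) before the deviance computation.

    Returns
    -------
    symmetric sample x sample DataFrame with zero diagonal.
    """
    counts = validate_counts(counts)
    if size_factors is None:
        size_factors = rle_size_factors(drop_all_zero_genes(counts))
    s = np.asarray(
        pd.Series(size_factors).reindex(counts.columns).to_numpy(), dtype=float
    )
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("size factors must be positive and cover all samples")
    x = counts.to_numpy(dtype=float)
    if transform == "sqrt":
        x = np.sqrt(x)
        s = np.sqrt(s)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        xi = x[:, [i]]
        xj = x[:, i + 1 :]
        si, sj = s[i], s[i + 1 :]
        shared = (xi + xj) / (si + sj)  # genes x remaining samples
        mi = si * shared
        mj = sj * shared
        # where both counts are zero the null fits exactly: contribution 0
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = np.where(
                shared > 0,
                _poisson_halfdev(xi, np.where(shared > 0, mi, 1.0))
                + _poisson_halfdev(xj, np.where(shared > 0, mj, 1.0)),
                0.0,
            )
        d[i, i + 1 :] = dev.sum(axis=0)
    d = d + d.T
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


def cluster_samples(
    d: pd.DataFrame,
    linkage_rule: str = "complete",
    n_clusters: int | None = None,
):
    """Agglomerative clustering of a sample dissimilarity matrix.

    Returns ``(linkage_matrix, leaf_order, labels)`` where ``leaf_order`` is
    the dendrogram leaf sequence (sample ids) and ``labels`` is a pandas
    Series of flat cluster ids (1-based) when ``n_clusters`` is given, else
    None.  Leaf order is deterministic given the input order.
    """
    dm = np.asarray(d, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    ids = list(d.index) if isinstance(d, pd.DataFrame) else list(range(len(dm)))
    if len(ids) == 1:
        warnings.warn("single sample: trivial one-leaf tree", stacklevel=2)
        labels = pd.Series([1], index=ids) if n_clusters else None
        return np.empty((0, 4)), ids, labels
    z = hierarchy.linkage(squareform(dm, checks=False), method=linkage_rule)
    order = hierarchy.leaves_list(z)
    leaf_order = [ids[i] for i in order]
    labels = None
    if n_clusters is not None:
        flat = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
        labels = pd.Series(flat, index=ids, name="cluster")
    return z, leaf_order, labels


class RLENormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios (RLE) count normalizer, sklearn layout.

    ``fit`` learns per-sample size factors from ``X`` (samples x genes);
    ``transform`` divides each sample row by its factor.  Because factors are
    per-*sample*, the transformer recomputes factors for new data in
    ``transform`` unless the fitted data is transformed (the common use);
    factors of the fitted data are exposed as ``size_factors_``.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_features=1)
        # genes x samples view for the shared implementation
        self.size_factors_ = rle_size_factors(pd.DataFrame(X.T)).to_numpy()
        self.n_features_in_ = X.shape[1]
        self._fitted_shape = X.shape
        return self

    def transform(self, X):
        check_is_fitted(self, "size_factors_")
        X = check_array(X, dtype=float)
        if X.shape[0] == self._fitted_shape[0]:
            factors = self.size_factors_
        else:
            factors = rle_size_factors(pd.DataFrame(X.T)).to_numpy()
        return X / factors[:, None]


class PoissonSampleClusterer(BaseEstimator):
    """Hierarchical sample clustering on the Poisson-deviance dissimilarity.

    Parameters
    ----------
    n_clusters : int
        Number of flat clusters cut from the dendrogram.
    linkage : str
        Linkage rule for :func:`scipy.cluster.hierarchy.linkage`.
    transform : None or "sqrt"
        Optional variance stabilization (see :func:`poisson_dissimilarity`).

    Attributes
    ----------
    size_factors_ : ndarray, RLE factors of the fitted samples.
    dissimilarity_ : ndarray, sample x sample distances.
    linkage_ : ndarray, scipy linkage matrix.
    leaf_order_ : list of int, dendrogram leaf order.
    labels_ : ndarray, flat cluster ids (1-based).
    """

    def __init__(self, n_clusters: int = 3, linkage: str = "complete",
                 transform: str | None = None):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.transform = transform

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        counts = pd.DataFrame(X.T)  # genes x samples
        counts = drop_all_zero_genes(counts)
        sf = rle_size_factors(counts)
        d = poisson_dissimilarity(counts, sf, transform=self.transform)
        z, order, labels = cluster_samples(
            d, linkage_rule=self.linkage, n_clusters=self.n_clusters
        )
        self.size_factors_ = sf.to_numpy()
        self.dissimilarity_ = d.to_numpy()
        self.linkage_ = z
        self.leaf_order_ = order
        self.labels_ = labels.to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
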