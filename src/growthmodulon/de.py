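"""Growth-rate-course differential expression.

Per condition, each gene's counts are regressed on the differential growth
rate mu with a cubic polynomial generalized linear model:

    log E[count_j] = log(s_j) + b0 + b1*mu_j + b2*mu_j^2 + b3*mu_j^3,

with s_j the RLE size factor of sample j.  The family is negative binomial
(variance m + phi*m^2) with the dispersion phi estimated by matching the
Pearson chi-square statistic to its residual degrees of freedom — by default
one dispersion pooled across all genes of the condition (the genes share the
design, and at ~11-15 samples per-gene estimates are too noisy to plug into
a test), with a per-gene mode available.  Significance is a quasi-likelihood
F-test of the cubic model against the intercept-only model: the deviance
drop per tested df over the Pearson scale, referenced to an F distribution
whose denominator df reflects how the dispersion was estimated.  P-values
are BH-adjusted across the genes of the condition.

Fitted log2 fold changes are evaluated on the condition's rate grid and
re-anchored to 0 at the reference rate (the highest rate, 0.4 1/h, by
default); a gene is called differentially expressed when its adjusted p-value
is below alpha and the maximum absolute fitted log2FC reaches the
condition-specific cutoff (0.73 for phosphate and nitrogen, 0.6 for carbon,
which lacks the lowest-rate sample).

All genes of a condition share one design matrix, so the IRLS solver is
vectorized across genes (batched p x p normal equations), which keeps
Monte-Carlo calibration studies cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from growthmodulon.counts import drop_all_zero_genes, rle_size_factors, validate_counts

__all__ = [
    "ProfileFit",
    "DEGSet",
    "RateCourseDE",
    "fit_rate_course",
    "fit_gene_profile",
    "call_degs",
    "benjamini_hochberg",
    "evaluate_log2fc",
    "DEFAULT_LFC_CUTOFFS",
]

#: shipped per-condition |log2FC| cutoffs; carbon is lower to compensate for
#: the missing lowest-rate sample
DEFAULT_LFC_CUTOFFS = {"phosphate": 0.73, "nitrogen": 0.73, "carbon": 0.6}

_ETA_CLIP = 30.0
_MAX_DISPERSION = 1e4


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Sorted ascending, ``adj_(i) = min_{j>=i} p_(j) * m / j`` capped at 1,
    returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# batched GLM internals


def _irls(Y, X, offset, dispersion=None, max_iter=80, tol=1e-10):
    """Batched IRLS for a log-link GLM shared across genes.

    Y : (G, n) counts; X : (n, p) design; offset : (n,) log size factors;
    dispersion : None for Poisson or a (G,) NB dispersion vector.
    Returns (beta (G, p), fitted mean (G, n)).
    """
    G, n = Y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    beta[:, 0] = np.log((Y.sum(axis=1) + 0.5) / np.exp(offset).sum())
    ridge = np.eye(p) * 1e-10
    for _ in range(max_iter):
        eta = np.clip(offset[None, :] + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        m = np.exp(eta)
        if dispersion is None:
            w = m
        else:
            w = m / (1.0 + dispersion[:, None] * m)
        z = (eta - offset[None, :]) + (Y - m) / m
        xtwx = np.einsum("gn,ni,nj->gij", w, X, X, optimize=True)
        xtwz = np.einsum("gn,ni->gi", w * z, X, optimize=True)
        new = np.linalg.solve(xtwx + ridge[None, :, :], xtwz[..., None])[..., 0]
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            break
    eta = np.clip(offset[None, :] + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    return beta, np.exp(eta)


def _loglik(Y, m, dispersion):
    """Per-gene log-likelihood row sums; dispersion 0 selects Poisson."""
    G = Y.shape[0]
    m = np.maximum(m, 1e-300)
    ll = np.empty(G)
    pois = dispersion <= 0
    if pois.any():
        Yp, mp = Y[pois], m[pois]
        ll[pois] = (special.xlogy(Yp, mp) - mp - special.gammaln(Yp + 1)).sum(axis=1)
    nb = ~pois
    if nb.any():
        a = dispersion[nb][:, None]
        Yn, mn = Y[nb], m[nb]
        r = 1.0 / a
        ll[nb] = (
            special.gammaln(Yn + r)
            - special.gammaln(r)
            - special.gammaln(Yn + 1)
            + special.xlogy(Yn, a * mn / (1.0 + a * mn))
            - r * np.log1p(a * mn)
        ).sum(axis=1)
    return ll


def _estimate_dispersion(Y, m, resid_df):
    """Per-gene NB dispersion by Pearson chi-square / df matching.

    Solves ``sum_j (y-m)^2 / (m + phi m^2) = n - p`` for phi >= 0 (bisection;
    phi = 0 when the gene is not overdispersed at the Poisson fit).
    """
    num = (Y - m) ** 2

    def chi2(phi):
        return (num / (m + phi[:, None] * m**2)).sum(axis=1)

    G = Y.shape[0]
    phi = np.zeros(G)
    need = chi2(phi) > resid_df
    if not need.any():
        return phi
    lo = np.zeros(need.sum())
    hi = np.ones(need.sum())
    Yn, mn = Y[need], m[need]
    numn = num[need]

    def chi2_sub(p):
        return (numn / (mn + p[:, None] * mn**2)).sum(axis=1)

    for _ in range(40):
        grow = chi2_sub(hi) > resid_df
        if not grow.any():
            break
        hi[grow] = np.minimum(hi[grow] * 4.0, _MAX_DISPERSION)
        if np.all(hi >= _MAX_DISPERSION):
            break
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        high_chi = chi2_sub(mid) > resid_df
        lo[high_chi] = mid[high_chi]
        hi[~high_chi] = mid[~high_chi]
    phi[need] = 0.5 * (lo + hi)
    return phi


def evaluate_log2fc(coefficients, grid, reference_mu) -> np.ndarray:
    """Fitted log2FC profile of a cubic (natural-log scale) coefficient
    vector over a rate grid, anchored to 0 at ``reference_mu``."""
    beta = np.asarray(coefficients, dtype=float)
    grid = np.asarray(grid, dtype=float)
    powers = np.arange(beta.size)
    f = (grid[:, None] ** powers[None, :]) @ beta
    f_ref = (float(reference_mu) ** powers) @ beta
    return (f - f_ref) / np.log(2.0)


# ---------------------------------------------------------------------------
# public fitting API


def fit_rate_course(
    counts,
    mu,
    size_factors=None,
    *,
    degree: int = 3,
    family: str = "auto",
    dispersion: str = "common",
    reference_mu: float | None = None,
    grid=None,
    condition: str = "",
) -> pd.DataFrame:
    """Fit the rate-course GLM for every gene of one condition.

    Parameters
    ----------
    counts : genes x samples DataFrame (or array) of raw counts.
    mu : per-sample differential growth rates (1/h).
    size_factors : per-sample RLE factors; computed from ``counts`` if None.
    degree : polynomial degree of the rate covariate (cubic by default).
    family : "auto" (negative binomial with estimated dispersion, Poisson
        fallback when underdispersed) or "poisson".
    dispersion : "common" (one Pearson-matched dispersion pooled across all
        genes; near-chi-square power) or "per-gene" (noisier, paid for by an
        F denominator with only n - p df).
    reference_mu : anchor rate for log2FC (default: highest grid rate).
    grid : rates at which fitted log2FC is reported (default: the distinct
        observed rates, sorted).

    Returns
    -------
    pandas.DataFrame indexed by gene with columns ``beta0..beta<degree>``,
    ``dispersion``, ``p_value``, ``p_adjusted``, ``r_squared``,
    ``max_abs_log2fc``, ``all_zero`` and one ``log2fc_<mu>`` column per grid
    rate.  The grid, reference and condition are stored in ``.attrs``.
    """
    counts = validate_counts(counts)
    mu = np.asarray(mu, dtype=float)
    n = counts.shape[1]
    if mu.shape != (n,):
        raise ValueError("mu must have one value per sample")
    distinct = np.unique(mu)
    if distinct.size < degree + 1:
        raise ValueError(
            f"cubic-in-mu model needs >= {degree + 1} distinct rates, "
            f"got {distinct.size}"
        )
    if n < degree + 2:
        raise ValueError("need residual degrees of freedom (n >= degree + 2)")
    if family not in ("auto", "nb", "negative-binomial", "poisson"):
        raise ValueError(f"unknown family {family!r}")

    if size_factors is None:
        size_factors = rle_size_factors(drop_all_zero_genes(counts))
    s = pd.Series(size_factors).reindex(counts.columns).to_numpy(dtype=float) \
        if isinstance(size_factors, pd.Series) else np.asarray(size_factors, float)
    if s.shape != (n,) or np.any(s <= 0):
        raise ValueError("size factors must be positive, one per sample")
    offset = np.log(s)

    if grid is None:
        grid = distinct
    grid = np.asarray(sorted(float(g) for g in grid))
    if reference_mu is None:
        reference_mu = float(grid[-1])

    Y_all = counts.to_numpy(dtype=float)
    nonzero = Y_all.sum(axis=1) > 0
    Y = Y_all[nonzero]
    G = Y.shape[0]

    # fit on a scaled basis z = mu / max|mu| for conditioning, map back after
    scale = np.max(np.abs(mu)) or 1.0
    z = mu / scale
    X_full = z[:, None] ** np.arange(degree + 1)[None, :]
    X_null = np.ones((n, 1))

    p_full = degree + 1
    if G > 0:
        resid_df = n - p_full
        beta_p, m_p = _irls(Y, X_full, offset)
        if family == "poisson":
            phi = np.zeros(G)
            beta_s, m_full = beta_p, m_p
        else:
            if dispersion == "common":
                # one dispersion pooled over all genes: solve the total
                # Pearson chi-square against the total residual df; its
                # estimation error is negligible, so the test below keeps
                # near-chi-square power
                phi_c = _estimate_dispersion(
                    Y.reshape(1, -1), m_p.reshape(1, -1), G * resid_df
                )[0]
                phi = np.full(G, phi_c)
            elif dispersion == "per-gene":
                phi = _estimate_dispersion(Y, m_p, resid_df)
            else:
                raise ValueError(f"unknown dispersion mode {dispersion!r}")
            if (phi > 0).any():
                beta_s, m_full = _irls(Y, X_full, offset, dispersion=phi)
            else:
                beta_s, m_full = beta_p, m_p
        _, m_null = _irls(Y, X_null, offset, dispersion=phi)
        ll_full = _loglik(Y, m_full, phi)
        ll_null = _loglik(Y, m_null, phi)
        ll_sat = _loglik(Y, Y, phi)
        dev_full = np.maximum(2.0 * (ll_sat - ll_full), 0.0)
        dev_null = np.maximum(2.0 * (ll_sat - ll_null), 0.0)
        # quasi-likelihood F-test: deviance drop per tested df over the
        # Pearson scale, referenced to F(df, denominator df).  The
        # denominator df is the df behind the dispersion estimate — per-gene:
        # n - p (propagating its uncertainty, which a plug-in chi-square LRT
        # ignores and becomes anti-conservative at ~10 samples); common:
        # the pooled G * (n - p), where the F reference approaches
        # chi-square(df)/df.
        if dispersion == "common" and family != "poisson":
            ql_scale = np.ones(G)
            denom_df = min(G * resid_df, 10**6)
        else:
            ql_scale = np.ones(G)
            pois_genes = phi <= 0  # Pearson-matched NB genes: scale 1 exactly
            if pois_genes.any():
                x2 = (
                    (Y[pois_genes] - m_full[pois_genes]) ** 2
                    / m_full[pois_genes]
                ).sum(axis=1)
                ql_scale[pois_genes] = np.maximum(1.0, x2 / resid_df)
            denom_df = resid_df
        f_stat = ((dev_null - dev_full) / degree) / ql_scale
        p_value = stats.f.sf(f_stat, degree, denom_df)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(dev_null > 1e-12, 1.0 - dev_full / dev_null, 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        beta = beta_s / (scale ** np.arange(degree + 1))[None, :]
        lfc = np.stack(
            [evaluate_log2fc(b, grid, reference_mu) for b in beta]
        )
    else:
        beta = np.zeros((0, p_full))
        phi = np.zeros(0)
        p_value = np.zeros(0)
        r2 = np.zeros(0)
        lfc = np.zeros((0, grid.size))

    # assemble including flagged all-zero genes (p = 1, flat profile)
    n_genes = counts.shape[0]
    full_beta = np.zeros((n_genes, p_full))
    full_phi = np.zeros(n_genes)
    full_p = np.ones(n_genes)
    full_r2 = np.zeros(n_genes)
    full_lfc = np.zeros((n_genes, grid.size))
    full_beta[nonzero] = beta
    full_phi[nonzero] = phi
    full_p[nonzero] = p_value
    full_r2[nonzero] = r2
    full_lfc[nonzero] = lfc

    out = pd.DataFrame(index=counts.index)
    for k in range(p_full):
        out[f"beta{k}"] = full_beta[:, k]
    out["dispersion"] = full_phi
    out["p_value"] = full_p
    out["p_adjusted"] = benjamini_hochberg(full_p)
    out["r_squared"] = full_r2
    for j, g in enumerate(grid):
        out[f"log2fc_{g:g}"] = full_lfc[:, j]
    out["max_abs_log2fc"] = np.abs(full_lfc).max(axis=1)
    out["all_zero"] = ~nonzero
    out.attrs["mu_grid"] = [float(g) for g in grid]
    out.attrs["reference_mu"] = float(reference_mu)
    out.attrs["condition"] = condition
    out.attrs["degree"] = degree
    return out


@dataclass
class ProfileFit:
    """Cubic rate-course regression result for a single gene."""

    gene_id: str
    condition: str
    coefficients: np.ndarray
    p_value: float
    p_adjusted: float
    r_squared: float
    log2fc: pd.Series  # indexed by grid rate, 0 at the reference
    max_abs_log2fc: float
    dispersion: float
    reference_mu: float


def fit_gene_profile(
    counts_for_gene,
    mu_per_sample,
    size_factors,
    family: str = "auto",
    *,
    dispersion: str = "common",
    gene_id: str = "",
    condition: str = "",
    reference_mu: float | None = None,
) -> ProfileFit:
    """Fit the rate-course GLM for one gene (see :func:`fit_rate_course`).

    With a single gene the BH adjustment is the identity, so
    ``p_adjusted == p_value``.
    """
    y = np.asarray(counts_for_gene, dtype=float)
    if size_factors is not None:
        size_factors = np.asarray(size_factors, dtype=float)
    counts = pd.DataFrame(
        y[None, :], index=[gene_id or "gene"],
        columns=[f"s{i}" for i in range(y.size)],
    )
    res = fit_rate_course(
        counts, mu_per_sample, size_factors,
        family=family, dispersion=dispersion,
        reference_mu=reference_mu, condition=condition,
    )
    row = res.iloc[0]
    grid = res.attrs["mu_grid"]
    degree = res.attrs["degree"]
    lfc = pd.Series(
        [row[f"log2fc_{g:g}"] for g in grid], index=grid, name="log2fc"
    )
    return ProfileFit(
        gene_id=gene_id or "gene",
        condition=condition,
        coefficients=row[[f"beta{k}" for k in range(degree + 1)]].to_numpy(),
        p_value=float(row["p_value"]),
        p_adjusted=float(row["p_adjusted"]),
        r_squared=float(row["r_squared"]),
        log2fc=lfc,
        max_abs_log2fc=float(row["max_abs_log2fc"]),
        dispersion=float(row["dispersion"]),
        reference_mu=res.attrs["reference_mu"],
    )


@dataclass
class DEGSet:
    """Genes of one condition passing significance and fold-change filters."""

    condition: str
    genes: set
    alpha: float
    log2fc_cutoff: float


def call_degs(
    fits,
    alpha: float = 0.05,
    log2fc_cutoff: float = 0.73,
    *,
    condition: str | None = None,
) -> DEGSet:
    """Call differentially expressed genes from one condition's fit table.

    ``fits`` is the DataFrame returned by :func:`fit_rate_course` (BH must
    have been applied across all genes of the condition, which
    :func:`fit_rate_course` does).  A gene is a DEG when
    ``p_adjusted < alpha`` and ``max_abs_log2fc >= log2fc_cutoff``.
    """
    if not isinstance(fits, pd.DataFrame) or len(fits) == 0:
        raise ValueError("fits must be a non-empty fit table")
    keep = (fits["p_adjusted"] < alpha) & (fits["max_abs_log2fc"] >= log2fc_cutoff)
    cond = condition if condition is not None else fits.attrs.get("condition", "")
    return DEGSet(
        condition=cond,
        genes=set(fits.index[keep]),
        alpha=alpha,
        log2fc_cutoff=log2fc_cutoff,
    )


class RateCourseDE(BaseEstimator):
    """Scikit-learn style estimator for rate-course differential expression.

    ``fit(X, y)`` takes ``X`` as a samples x genes count matrix and ``y`` as
    the per-sample differential growth rate; RLE size factors are computed
    internally unless passed.

    Parameters
    ----------
    degree : polynomial degree in mu (default 3).
    family : "auto" (NB, Poisson fallback) or "poisson".
    alpha : BH-adjusted significance level for DEG calling.
    lfc_cutoff : minimum max |log2FC| over the grid for DEG calling.
    reference_mu : anchor rate for log2FC; default the highest observed rate.

    Attributes
    ----------
    results_ : per-gene fit table (see :func:`fit_rate_course`).
    p_values_, p_adjusted_, max_abs_log2fc_, r_squared_, dispersion_ : arrays.
    coef_ : (n_genes, degree+1) polynomial coefficients (natural-log scale).
    log2fc_ : (n_genes, n_grid) fitted log2FC profiles.
    mu_grid_, reference_mu_ : evaluation grid and anchor.
    degs_ : indices of genes passing both filters.
    """

    def __init__(self, degree: int = 3, family: str = "auto",
                 dispersion: str = "common", alpha: float = 0.05,
                 lfc_cutoff: float = 0.73,
                 reference_mu: float | None = None):
        self.degree = degree
        self.family = family
        self.dispersion = dispersion
        self.alpha = alpha
        self.lfc_cutoff = lfc_cutoff
        self.reference_mu = reference_mu

    def fit(self, X, y, size_factors=None):
        if isinstance(X, pd.DataFrame):
            counts = X.T
        else:
            X = np.asarray(X, dtype=float)
            counts = pd.DataFrame(
                X.T, index=[f"g{i}" for i in range(X.shape[1])],
                columns=[f"s{j}" for j in range(X.shape[0])],
            )
        res = fit_rate_course(
            counts, y, size_factors,
            degree=self.degree, family=self.family,
            dispersion=self.dispersion, reference_mu=self.reference_mu,
        )
        self.results_ = res
        self.n_features_in_ = counts.shape[0]
        self.coef_ = res[[f"beta{k}" for k in range(self.degree + 1)]].to_numpy()
        self.p_values_ = res["p_value"].to_numpy()
        self.p_adjusted_ = res["p_adjusted"].to_numpy()
        self.r_squared_ = res["r_squared"].to_numpy()
        self.dispersion_ = res["dispersion"].to_numpy()
        self.mu_grid_ = np.asarray(res.attrs["mu_grid"])
        self.reference_mu_ = res.attrs["reference_mu"]
        self.log2fc_ = res[
            [f"log2fc_{g:g}" for g in self.mu_grid_]
        ].to_numpy()
        self.max_abs_log2fc_ = res["max_abs_log2fc"].to_numpy()
        self.degs_ = np.flatnonzero(
            (self.p_adjusted_ < self.alpha)
            & (self.max_abs_log2fc_ >= self.lfc_cutoff)
        )
        return self

    def predict(self, mu):
        """Fitted log2FC profiles of all genes at the given rates."""
        check_is_fitted(self, "coef_")
        return np.stack(
            [evaluate_log2fc(b, mu, self.reference_mu_) for b in self.coef_]
        )
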