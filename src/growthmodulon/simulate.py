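"""Synthetic-data generator with planted ground truth.

Emulates the design of a three-condition growth-rate-transition RNA-Seq
experiment: pre-cultures limited in phosphate, nitrogen or carbon, sampled at
target differential growth rates {0, 0.1, 0.2, 0.3, 0.4} 1/h with three
biological replicates each.  Two replicates (C2-0.1 and N3-0.2) are dropped
from the default design and no mu = 0 sample exists for carbon (its lag phase
is too short to sample), giving 15 + 14 + 11 = 40 samples.

Counts are negative-binomial via a gamma-Poisson mixture (variance
``m + phi*m^2``); a planted modulon follows one of four canonical
log2-fold-change profiles over the rate grid in *every* condition, while
condition-private differentially expressed genes respond in only one or two
conditions.  A synthetic regulatory network plants enriched regulons whose
targets are drawn preferentially from the modulon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from growthmodulon.kinetics import GrowthSeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_profile_templates",
    "simulate_counts",
    "simulate_network",
    "simulate_gene_sets",
    "simulate_growth_curve",
    "DEFAULT_CONDITIONS",
    "DEFAULT_MU_GRID",
]

DEFAULT_CONDITIONS = ("phosphate", "nitrogen", "carbon")
DEFAULT_MU_GRID = (0.0, 0.1, 0.2, 0.3, 0.4)
#: replicates rejected in quality assessment in the emulated design
DEFAULT_DROPPED = (("carbon", 2, 0.1), ("nitrogen", 3, 0.2))
#: (condition, mu) points absent from the design: carbon has no mu = 0 sample
DEFAULT_SKIPPED_POINTS = (("carbon", 0.0),)

# lag (h) before growth acceleration, per pre-culture condition; the ramp to
# mu_max is ~6 h in all conditions
_NOMINAL_LAG_H = {"phosphate": 4.0, "nitrogen": 10.0, "carbon": 0.5}
_NOMINAL_RAMP_H = 6.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design.

    Defaults reproduce the emulated experiment: 3 conditions x rate grid
    {0..0.4} x 3 replicates, minus the carbon mu = 0 point and two rejected
    replicates; ~3,000 genes with a planted 400-gene modulon split over four
    profile clusters at amplitude 1.5 log2 units; NB dispersion 0.02;
    log-uniform library sizes in [5e6, 2e7]; 50 regulons of 10-40 targets of
    which 5 are planted as enriched in the modulon.
    """

    n_genes: int = 3000
    conditions: tuple = DEFAULT_CONDITIONS
    mu_grid: tuple = DEFAULT_MU_GRID
    replicates_per_point: int = 3
    dropped_samples: tuple = DEFAULT_DROPPED
    skipped_points: tuple = DEFAULT_SKIPPED_POINTS
    modulon_size: int = 400
    cluster_proportions: tuple = (0.25, 0.25, 0.25, 0.25)
    amplitude_log2: float = 1.5
    nb_dispersion: float = 0.02
    library_size_range: tuple = (5e6, 2e7)
    condition_private_deg_count: int = 150
    n_regulons: int = 50
    regulon_size_range: tuple = (10, 40)
    planted_enriched_regulons: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.mu_grid = tuple(float(m) for m in self.mu_grid)
        self.dropped_samples = tuple(
            (c, int(r), float(m)) for c, r, m in self.dropped_samples
        )
        self.skipped_points = tuple(
            (c, float(m)) for c, m in self.skipped_points
        )
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "replicates_per_point"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in (
            "modulon_size",
            "condition_private_deg_count",
            "n_regulons",
            "planted_enriched_regulons",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if len(self.cluster_proportions) != 4 or any(
            p < 0 for p in self.cluster_proportions
        ):
            raise ValueError("cluster_proportions must be 4 non-negative fractions")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        if self.modulon_size + self.condition_private_deg_count > self.n_genes:
            raise ValueError(
                "modulon_size + condition_private_deg_count exceeds n_genes"
            )
        if list(self.mu_grid) != sorted(self.mu_grid):
            raise ValueError("mu_grid must be sorted ascending")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must satisfy 0 < min <= max")
        slo, shi = self.regulon_size_range
        if not (1 <= slo <= shi):
            raise ValueError("regulon_size_range must satisfy 1 <= min <= max")
        if shi > self.n_genes:
            raise ValueError("regulon sizes cannot exceed n_genes")
        if self.planted_enriched_regulons > self.n_regulons:
            raise ValueError("planted_enriched_regulons exceeds n_regulons")
        full = {
            (c, r, m)
            for c in self.conditions
            for m in self.condition_grid(c)
            for r in range(1, self.replicates_per_point + 1)
        }
        for trip in self.dropped_samples:
            if trip not in full:
                raise ValueError(
                    f"dropped sample {trip} does not exist in the full design"
                )

    def condition_grid(self, condition: str) -> tuple:
        """Rate grid actually sampled for one condition."""
        skipped = {m for c, m in self.skipped_points if c == condition}
        return tuple(m for m in self.mu_grid if m not in skipped)

    def design_table(self) -> pd.DataFrame:
        """Enumerate the sample design (after skips and drops)."""
        dropped = set(self.dropped_samples)
        rows = []
        for cond in self.conditions:
            lag = _NOMINAL_LAG_H.get(cond, 2.0)
            mu_max = max(self.mu_grid)
            for m in self.condition_grid(cond):
                for rep in range(1, self.replicates_per_point + 1):
                    if (cond, rep, m) in dropped:
                        continue
                    frac = m / mu_max if mu_max > 0 else 0.0
                    rows.append(
                        {
                            "sample_id": f"{cond[0].upper()}{rep}-{m:g}",
                            "condition": cond,
                            "replicate": rep,
                            "mu": m,
                            "time_h": round(lag + frac * _NOMINAL_RAMP_H, 3),
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Planted truth of one simulation.

    ``mean_profile`` maps ``(gene, condition, mu)`` to the expected log2
    expression relative to the reference rate (the last grid point) and is
    stored only for genes with a planted effect; all other genes are flat
    (implicitly zero).
    """

    modulon_genes: set
    cluster_of_gene: dict
    private_deg_genes: dict
    enriched_regulators: set
    mean_profile: dict

    def __post_init__(self) -> None:
        if set(self.cluster_of_gene) != set(self.modulon_genes):
            raise ValueError("cluster_of_gene keys must equal modulon_genes")


def _template_log2fc(
    cluster: int, mu: float, mu_lo: float, mu_ref: float, mu_penult: float,
    amplitude: float,
) -> float:
    """Canonical log2FC-vs-reference profile value for one cluster at ``mu``.

    All four shapes are anchored to 0 at the reference rate ``mu_ref``:

    1. steady increase toward the reference (from -a to 0);
    2. flat at -a on the lower half of the rate range, then a sharp rise;
    3. increase up to the penultimate grid rate, decrease on the last interval;
    4. steady decrease toward the reference (from +a to 0).
    """
    a = amplitude
    u = (mu - mu_lo) / (mu_ref - mu_lo)
    if cluster == 1:
        return a * (u - 1.0)
    if cluster == 2:
        return -a if u <= 0.5 else -2.0 * a * (1.0 - u)
    if cluster == 3:
        ub = (mu_penult - mu_lo) / (mu_ref - mu_lo)
        if u <= ub:
            return -0.5 * a + 1.5 * a * u / ub
        return a * (1.0 - u) / (1.0 - ub)
    if cluster == 4:
        return a * (1.0 - u)
    raise ValueError(f"unknown cluster {cluster}")


def make_profile_templates(mu_grid, amplitude_log2: float) -> dict:
    """The four canonical expression-profile templates over a rate grid.

    Parameters
    ----------
    mu_grid : sequence of float
        Sorted ascending growth rates; the last element is the reference.
    amplitude_log2 : float
        Profile amplitude in log2 units (total span of cluster 1/4 profiles).

    Returns
    -------
    dict mapping cluster id (1-4) to a log2FC vector over ``mu_grid``, each
    equal to 0 at the reference rate.
    """
    grid = [float(m) for m in mu_grid]
    if len(grid) < 3:
        raise ValueError("need at least 3 rate grid points for cubic-like shapes")
    if grid != sorted(grid):
        raise ValueError("mu_grid must be sorted ascending")
    lo, ref, penult = grid[0], grid[-1], grid[-2]
    return {
        c: np.array(
            [_template_log2fc(c, m, lo, ref, penult, amplitude_log2) for m in grid]
        )
        for c in (1, 2, 3, 4)
    }


def _gene_ids(n: int) -> list:
    return [f"cg{i:04d}" for i in range(1, n + 1)]


def _allocate_clusters(n: int, proportions) -> list:
    """Largest-remainder allocation of n genes over 4 clusters."""
    raw = [p * n for p in proportions]
    base = [int(math.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)], kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    out = []
    for cluster, count in enumerate(base, start=1):
        out.extend([cluster] * count)
    return out


def simulate_counts(config: SimulationConfig):
    """Simulate a gene x sample count matrix with planted structure.

    Returns
    -------
    counts : pandas.DataFrame
        Non-negative integer counts, genes x samples.
    meta : pandas.DataFrame
        Sample metadata (sample_id, condition, replicate, mu, time_h).
    truth : GroundTruth
        Planted modulon, clusters, private DEGs and mean profiles.

    Bit-reproducible for a fixed ``config`` (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = config.design_table()
    genes = _gene_ids(config.n_genes)
    mu_max = max(config.mu_grid)
    mu_lo = min(config.mu_grid)
    mu_penult = sorted(config.mu_grid)[-2]

    # gene roles
    perm = rng.permutation(config.n_genes)
    modulon_idx = perm[: config.modulon_size]
    private_idx = perm[
        config.modulon_size : config.modulon_size + config.condition_private_deg_count
    ]
    clusters = _allocate_clusters(config.modulon_size, config.cluster_proportions)
    cluster_of = {genes[i]: c for i, c in zip(modulon_idx, clusters)}

    # condition-private genes: a random shape in a random 1-2 conditions,
    # flat elsewhere -> excluded from the modulon by construction
    private_assign = {}
    private_by_cond = {c: set() for c in config.conditions}
    for i in private_idx:
        n_conds = int(rng.integers(1, 3))
        conds = tuple(
            rng.choice(len(config.conditions), size=n_conds, replace=False)
        )
        shape = int(rng.integers(1, 5))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        private_assign[i] = (conds, shape, sign)
        for ci in conds:
            private_by_cond[config.conditions[ci]].add(genes[i])

    # baseline relative abundances: heavy-tailed log-normal
    base_weight = rng.lognormal(mean=0.0, sigma=1.3, size=config.n_genes)

    # per-gene, per-condition, per-mu expected log2FC vs reference
    cond_index = {c: k for k, c in enumerate(config.conditions)}
    delta = np.zeros(
        (config.n_genes, len(config.conditions), len(config.mu_grid))
    )
    mu_pos = {m: j for j, m in enumerate(config.mu_grid)}
    for i in modulon_idx:
        c = cluster_of[genes[i]]
        for j, m in enumerate(config.mu_grid):
            val = _template_log2fc(
                c, m, mu_lo, mu_max, mu_penult, config.amplitude_log2
            )
            delta[i, :, j] = val
    for i, (conds, shape, sign) in private_assign.items():
        for ci in conds:
            for j, m in enumerate(config.mu_grid):
                delta[i, ci, j] = sign * _template_log2fc(
                    shape, m, mu_lo, mu_max, mu_penult, config.amplitude_log2
                )

    # library sizes: log-uniform
    lo, hi = config.library_size_range
    n_samples = len(meta)
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    counts = np.zeros((config.n_genes, n_samples), dtype=np.int64)
    phi = config.nb_dispersion
    for s in range(n_samples):
        ci = cond_index[meta.iloc[s]["condition"]]
        j = mu_pos[float(meta.iloc[s]["mu"])]
        nu = base_weight * np.exp2(delta[:, ci, j])
        m = lib[s] * nu / nu.sum()
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=m * phi)
            counts[:, s] = rng.poisson(lam)
        else:
            counts[:, s] = rng.poisson(m)

    counts_df = pd.DataFrame(counts, index=genes, columns=meta["sample_id"].tolist())
    counts_df.index.name = "gene_id"

    mean_profile = {}
    for i in np.concatenate([modulon_idx, private_idx]).astype(int):
        g = genes[i]
        for cond in config.conditions:
            ci = cond_index[cond]
            for m in config.condition_grid(cond):
                mean_profile[(g, cond, m)] = float(delta[i, ci, mu_pos[m]])

    truth = GroundTruth(
        modulon_genes=set(cluster_of),
        cluster_of_gene=cluster_of,
        private_deg_genes=private_by_cond,
        enriched_regulators=set(),  # filled by simulate_network
        mean_profile=mean_profile,
    )
    return counts_df, meta, truth


def simulate_network(
    config: SimulationConfig,
    truth: GroundTruth,
    *,
    planted_modulon_fraction: float = 0.6,
) -> pd.DataFrame:
    """Simulate a regulator -> target edge list with planted enriched regulons.

    The first ``config.planted_enriched_regulons`` regulators draw
    ``planted_modulon_fraction`` (>= 0.5) of their targets from the modulon;
    the remaining regulons sample targets uniformly.  Regulator ids are
    themselves gene ids (regulators are genes), drawn outside the modulon.
    The returned edge list contains no duplicate (regulator, target) pairs.

    The planted regulator ids are recorded in ``truth.enriched_regulators``.
    """
    if not 0.5 <= planted_modulon_fraction <= 1.0:
        raise ValueError("planted_modulon_fraction must be in [0.5, 1]")
    genes = _gene_ids(config.n_genes)
    modulon = sorted(truth.modulon_genes)
    non_modulon = sorted(set(genes) - truth.modulon_genes)
    if config.planted_enriched_regulons > 0 and not modulon:
        raise ValueError("cannot plant enriched regulons with an empty modulon")
    slo, shi = config.regulon_size_range
    if shi > config.n_genes:
        raise ValueError("regulon size exceeds the number of genes")

    rng = np.random.default_rng((config.seed, 7))
    regulators = list(
        rng.choice(non_modulon if non_modulon else genes,
                   size=config.n_regulons, replace=False)
    )
    edges = []
    planted = set()
    for r_idx, reg in enumerate(regulators):
        size = int(rng.integers(slo, shi + 1))
        pool = [g for g in genes if g != reg]
        if r_idx < config.planted_enriched_regulons:
            n_in = int(math.ceil(planted_modulon_fraction * size))
            n_in = min(n_in, len(modulon))
            inside = list(rng.choice(modulon, size=n_in, replace=False))
            outside_pool = [g for g in non_modulon if g != reg]
            outside = list(
                rng.choice(outside_pool, size=size - n_in, replace=False)
            )
            targets = inside + outside
            planted.add(reg)
        else:
            targets = list(rng.choice(pool, size=size, replace=False))
        edges.extend((reg, t) for t in targets)
    truth.enriched_regulators = planted
    out = pd.DataFrame(edges, columns=["regulator", "target"])
    if out.duplicated().any():  # impossible by construction, cheap to assert
        raise AssertionError("duplicate edges generated")
    return out


def simulate_gene_sets(
    config: SimulationConfig,
    truth: GroundTruth,
    *,
    n_sets: int = 20,
    size_range: tuple = (15, 60),
    planted: int = 2,
    planted_modulon_fraction: float = 0.6,
) -> dict:
    """Synthetic gene-set collection (GMT-shaped): ``{set_id: gene list}``.

    Mirrors :func:`simulate_network` but for anonymous pathway-like sets;
    the first ``planted`` sets are enriched in the modulon.
    """
    genes = _gene_ids(config.n_genes)
    modulon = sorted(truth.modulon_genes)
    rng = np.random.default_rng((config.seed, 13))
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if i < planted and modulon:
            n_in = min(int(math.ceil(planted_modulon_fraction * size)), len(modulon))
            inside = list(rng.choice(modulon, size=n_in, replace=False))
            outside = list(
                rng.choice(
                    sorted(set(genes) - set(inside)), size=size - n_in, replace=False
                )
            )
            members = inside + outside
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        sets[f"GS{i + 1:03d}"] = members
    return sets


def simulate_growth_curve(
    viability_percent: float = 100.0,
    lag_h: float = 4.0,
    mu_max: float = 0.4,
    noise_sd: float = 0.0,
    *,
    ramp_h: float = _NOMINAL_RAMP_H,
    initial_cdw: float = 1.2,
    t_end: float | None = None,
    dt: float = 0.25,
    condition: str = "",
    seed: int | None = None,
) -> GrowthSeries:
    """Simulate a CDW trajectory through a lag and growth-rate ramp.

    Total biomass = constant dead fraction + viable fraction growing with a
    piecewise-linear instantaneous rate mu(t): 0 during the lag, rising
    linearly to ``mu_max`` over ``ramp_h`` hours, then constant.  The sampling
    grid includes the ramp knots so the rate is exactly linear between
    consecutive samples (interval log-ratios then equal mu at interval
    midpoints).  Additive Gaussian measurement noise on CDW, floored to stay
    positive.
    """
    if not (0 < viability_percent <= 100):
        raise ValueError("viability must be in (0, 100]")
    if mu_max <= 0:
        raise ValueError("mu_max must be positive")
    if t_end is None:
        t_end = lag_h + ramp_h + 2.0
    knots = np.array([0.0, lag_h, lag_h + ramp_h, t_end])
    times = np.union1d(np.arange(0.0, t_end + dt / 2, dt), knots)
    times = times[times <= t_end + 1e-12]
    mu_t = np.interp(times, knots, [0.0, 0.0, mu_max, mu_max])
    # cumulative integral of piecewise-linear mu(t): trapezoid is exact
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (mu_t[1:] + mu_t[:-1]) * np.diff(times))]
    )
    v_frac = viability_percent / 100.0
    viable = v_frac * initial_cdw * np.exp(cum)
    dead = initial_cdw * (1.0 - v_frac)
    cdw = viable + dead
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cdw = cdw + rng.normal(0.0, noise_sd, size=cdw.size)
        cdw = np.maximum(cdw, 1e-6)
    return GrowthSeries(
        time=times,
        cdw=cdw,
        viability_at_inoculation=viability_percent,
        condition=condition,
    )
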