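"""Growth kinetics: viability-adjusted differential growth rates.

Cell-dry-weight (CDW) measurements do not distinguish viable from dead cells.
After a long stationary pre-culture a fraction of the inoculum is dead, so the
specific growth rate computed from raw CDW underestimates the rate of the
viable population early in the batch.  The differential growth rate between
two consecutive CDW measurements is therefore computed on the viable biomass,

    mu_diff(t) = ln( (c_t - d) / (c_{t-1} - d) ) / (t - t_{t-1}),

where ``d = c_0 * (1 - v0/100)`` is the dead-biomass offset implied by the
percent viability ``v0`` measured at inoculation.  With ``v0 = 100`` this is
the ordinary log-ratio specific growth rate.  A ``strict_as_printed`` mode
subtracting ``c_0 * v0/100`` instead is kept for comparison; it is not the
default because at full viability it would subtract the entire inoculum.

Between measurement intervals, mu is interpolated linearly between interval
midpoints (each interval's mu_diff is attributed to its midpoint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthSeries",
    "MuSeries",
    "viability_percent",
    "mu_differential",
    "mu_at",
    "select_samples",
    "substrate_depletion_time",
]


@dataclass
class GrowthSeries:
    """A timestamped biomass series for one culture.

    Parameters
    ----------
    time : array-like of float
        Sampling times in hours, strictly increasing.  The first entry is the
        inoculation point (t = 0 by convention).
    cdw : array-like of float
        Cell dry weight in g/L, strictly positive.
    viability_at_inoculation : float
        Percent viability of the inoculum, in (0, 100].
    condition : str
        Free-text label of the pre-culture condition.
    """

    time: np.ndarray
    cdw: np.ndarray
    viability_at_inoculation: float = 100.0
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cdw = np.asarray(self.cdw, dtype=float)
        if self.time.ndim != 1 or self.cdw.ndim != 1:
            raise ValueError("time and cdw must be one-dimensional")
        if self.time.shape != self.cdw.shape:
            raise ValueError("time and cdw must have the same length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.cdw <= 0):
            raise ValueError("cdw must be strictly positive")
        v = float(self.viability_at_inoculation)
        if not (0.0 < v <= 100.0):
            raise ValueError(
                f"viability_at_inoculation must be in (0, 100], got {v}"
            )
        self.viability_at_inoculation = v

    def __len__(self) -> int:
        return self.time.size


@dataclass
class MuSeries:
    """Per-interval differential growth rates attributed to interval midpoints.

    ``mu_diff[i]`` is the viability-adjusted rate over
    ``(time_bounds` intervals); evaluating the piecewise-linear interpolation
    at ``midpoint_time[i]`` returns ``mu_diff[i]`` exactly.  Values may be
    negative during a lag phase (biomass decline) and are not clipped.
    """

    midpoint_time: np.ndarray
    mu_diff: np.ndarray
    time_bounds: tuple[float, float]
    condition: str = ""

    def __post_init__(self) -> None:
        self.midpoint_time = np.asarray(self.midpoint_time, dtype=float)
        self.mu_diff = np.asarray(self.mu_diff, dtype=float)
        if self.midpoint_time.shape != self.mu_diff.shape:
            raise ValueError("midpoint_time and mu_diff must match in length")

    @property
    def segments(self) -> pd.DataFrame:
        """Linear coefficients (slope, intercept) of mu(t) between midpoints."""
        t, m = self.midpoint_time, self.mu_diff
        if t.size < 2:
            return pd.DataFrame(columns=["t_start", "t_end", "slope", "intercept"])
        slope = np.diff(m) / np.diff(t)
        intercept = m[:-1] - slope * t[:-1]
        return pd.DataFrame(
            {"t_start": t[:-1], "t_end": t[1:], "slope": slope, "intercept": intercept}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.midpoint_time, "mu_diff_per_h": self.mu_diff}
        )


def viability_percent(
    cfu_per_ml_sample: float, cfu_per_ml_reference: float
) -> float:
    """Percent viability of a sample relative to a mid-exponential reference.

    100% viability is defined by the colony-forming-unit density of a
    mid-exponential reference culture; values above 100 are possible (e.g.
    counting noise) and are flagged with a warning, not clipped.
    """
    if cfu_per_ml_reference <= 0:
        raise ValueError("reference CFU density must be positive")
    if cfu_per_ml_sample < 0:
        raise ValueError("sample CFU density must be non-negative")
    v = 100.0 * cfu_per_ml_sample / cfu_per_ml_reference
    if v > 100.0:
        warnings.warn(
            f"viability {v:.1f}% exceeds 100% of the reference", stacklevel=2
        )
    return v


def mu_differential(
    series: GrowthSeries, *, strict_as_printed: bool = False
) -> MuSeries:
    """Viability-adjusted differential growth rate per measurement interval.

    Parameters
    ----------
    series : GrowthSeries
        Biomass series with at least two time points.
    strict_as_printed : bool
        If True, subtract the *viable* inoculum biomass ``c_0 * v0/100``
        instead of the dead-biomass offset ``c_0 * (1 - v0/100)``.  This
        variant is kept only for comparison; at ``v0 = 100`` it removes the
        entire inoculum and is rarely meaningful.

    Returns
    -------
    MuSeries
        One rate per consecutive CDW pair, attributed to the interval
        midpoint, in 1/h.
    """
    if len(series) < 2:
        raise ValueError("need at least two time points to compute rates")
    v0 = series.viability_at_inoculation
    c0 = series.cdw[0]
    if strict_as_printed:
        offset = c0 * v0 / 100.0
    else:
        offset = c0 * (1.0 - v0 / 100.0)
    viable = series.cdw - offset
    bad = np.flatnonzero(viable <= 0)
    if bad.size:
        t_bad = series.time[bad[0]]
        raise ValueError(
            f"non-positive viable biomass at t = {t_bad:g} h "
            f"(cdw = {series.cdw[bad[0]]:g}, offset = {offset:g})"
        )
    dt = np.diff(series.time)
    mu = np.log(viable[1:] / viable[:-1]) / dt
    mid = 0.5 * (series.time[1:] + series.time[:-1])
    return MuSeries(
        midpoint_time=mid,
        mu_diff=mu,
        time_bounds=(float(series.time[0]), float(series.time[-1])),
        condition=series.condition,
    )


def mu_at(series: MuSeries, t):
    """Interpolated growth rate at time(s) ``t``.

    Piecewise-linear between interval midpoints; constant beyond the outer
    midpoints but still inside the observed time range.  Times outside the
    observed range are rejected rather than extrapolated.
    """
    t_arr = np.asarray(t, dtype=float)
    lo, hi = series.time_bounds
    if np.any(t_arr < lo) or np.any(t_arr > hi):
        raise ValueError(
            f"time outside the observed range [{lo:g}, {hi:g}] h"
        )
    out = np.interp(t_arr, series.midpoint_time, series.mu_diff)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def select_samples(
    candidates,
    series: MuSeries,
    targets,
) -> pd.DataFrame:
    """Pick, per target growth rate, the candidate sample whose interpolated
    rate is closest.

    Parameters
    ----------
    candidates : sequence of (sample_id, time_h)
        Transcriptome samples available for selection; times must lie inside
        the observed range of ``series``.
    series : MuSeries
        Interpolatable rate series.
    targets : sequence of float
        Target growth rates in 1/h.

    Returns
    -------
    pandas.DataFrame
        Columns ``target_mu, sample_id, time_h, achieved_mu, reused``; ties on
        |mu - target| are broken by the earliest sampling time.  ``reused``
        flags samples serving more than one target.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    ids = [c[0] for c in candidates]
    times = np.array([float(c[1]) for c in candidates])
    order = np.argsort(times, kind="stable")  # earliest-time tie-break
    mus = mu_at(series, times)
    rows = []
    for target in targets:
        err = np.abs(mus[order] - float(target))
        best = order[int(np.argmin(err))]  # argmin takes first min -> earliest
        rows.append(
            {
                "target_mu": float(target),
                "sample_id": ids[best],
                "time_h": times[best],
                "achieved_mu": float(mus[best]),
            }
        )
    out = pd.DataFrame(rows)
    out["reused"] = out["sample_id"].duplicated(keep=False)
    if out["reused"].any():
        warnings.warn(
            "one sample serves multiple target growth rates", stacklevel=2
        )
    return out


def substrate_depletion_time(
    concentration_mmol_per_l: float,
    uptake_mmol_per_gcdw_h: float,
    biomass_g_per_l: float,
) -> float:
    """Time (h) to deplete a medium component at a constant biomass-specific
    uptake rate.

    Assumes zero-order (saturated) uptake kinetics and constant biomass, a
    conservative upper bound immediately after inoculation:
    ``t = c / (q * X)``.  Used e.g. to show that protocatechuic acid (0.2 mM,
    uptake 2.04 mmol/gCDW/h, 1.2 gCDW/L) is exhausted well within the first
    hour of a batch.
    """
    if concentration_mmol_per_l < 0:
        raise ValueError("concentration must be non-negative")
    if uptake_mmol_per_gcdw_h <= 0 or biomass_g_per_l <= 0:
        raise ValueError("uptake rate and biomass must be positive")
    return concentration_mmol_per_l / (uptake_mmol_per_gcdw_h * biomass_g_per_l)
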