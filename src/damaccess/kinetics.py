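"""Methylation kinetics: summaries, rate fits, limits, relative rates.

First-order kinetics with full accessibility gives
``f(t) = 1 - exp(-k t)``, so ``ln(1 - f)`` is linear in time with slope
``-k``; the log-linear fit estimates the rate of any subset's summary
time course. Regions that are accessible in only a fraction ``A`` of
cells saturate instead: ``f(t) = A (1 - exp(-k t))``, fitted by bounded
nonlinear least squares. A subset's rate divided by the genome-wide
reference rate is its relative rate, the unit the analyses report.

The log-linear fit keeps a free intercept: a shared onset lag of enzyme
expression shifts the intercept of every subset identically and relative
rates are intercept-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .quantify import MethylationTrack


@dataclass
class TimeCourse:
    """Summary of a site subset over time: central statistic plus a
    percentile band and the number of contributing sites."""

    timepoints: np.ndarray
    values: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    n_sites: np.ndarray
    statistic: str = "median"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timepoint": self.timepoints,
                "value": self.values,
                "band_lower": self.band_lower,
                "band_upper": self.band_upper,
                "n_sites": self.n_sites,
            }
        )


@dataclass
class KineticFit:
    """Log-linear rate fit: ln(1 - f) = intercept - k t."""

    k: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class SaturatingFit:
    """Saturating fit f(t) = A (1 - exp(-k t)); A is the accessibility limit."""

    A: float
    k: float
    rss: float
    k_identifiable: bool = True


@dataclass
class RelativeRate:
    """Subset rate normalised to a reference (genome-wide) rate."""

    r: float


def summarize_timecourse(
    track: MethylationTrack,
    site_subset=None,
    statistic: str = "median",
    band: tuple[float, float] = (5.0, 95.0),
) -> TimeCourse:
    """Per-time-point summary over a site subset.

    ``site_subset``: site ids (index values of ``track.sites``) or None
    for all sites. Percentiles use linear interpolation between order
    statistics so bands are reproducible bit for bit.
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    frame = track.fractions
    if site_subset is not None:
        frame = frame.loc[frame.index.intersection(pd.Index(site_subset))]
    tps = np.array(sorted(float(c) for c in frame.columns))
    values, lo, hi, n = [], [], [], []
    for t in tps:
        vals = frame[t].dropna().to_numpy()
        n.append(vals.size)
        if vals.size == 0:
            values.append(np.nan)
            lo.append(np.nan)
            hi.append(np.nan)
            continue
        values.append(np.median(vals) if statistic == "median" else np.mean(vals))
        lo.append(np.percentile(vals, band[0]))
        hi.append(np.percentile(vals, band[1]))
    if all(c == 0 for c in n):
        raise ValueError("site subset empty (after missingness) at all timepoints")
    return TimeCourse(
        timepoints=tps,
        values=np.array(values),
        band_lower=np.array(lo),
        band_upper=np.array(hi),
        n_sites=np.array(n),
        statistic=statistic,
    )


def _log_linear(t: np.ndarray, values: np.ndarray, clip_eps: float) -> KineticFit:
    mask = np.isfinite(values)
    t, values = t[mask], values[mask]
    if np.all(values >= 1.0):
        raise ValueError("saturated time course; use fit_saturating")
    if t.size < 2:
        raise ValueError("need >= 2 timepoints with defined values")
    y = np.log(1.0 - np.minimum(values, 1.0 - clip_eps))
    if np.allclose(y, y[0]):
        # constant course (e.g. all zeros): slope 0, perfect fit of a constant
        return KineticFit(k=0.0, intercept=float(y[0]), r_squared=1.0, n_points=t.size)
    res = stats.linregress(t, y)
    return KineticFit(
        k=max(0.0, -float(res.slope)),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=int(t.size),
    )


def fit_log_linear(tc: TimeCourse, clip_eps: float = 1e-6) -> KineticFit:
    """Rate from ordinary least squares of ln(1 - f) on time.

    Values >= 1 are clipped to ``1 - clip_eps`` before the log; a time
    course saturated at 1 everywhere is an error (fit the saturating
    model instead). The rate is floored at 0.
    """
    return _log_linear(np.asarray(tc.timepoints, float), np.asarray(tc.values, float), clip_eps)


def fit_saturating(tc: TimeCourse, max_iter: int = 10_000) -> SaturatingFit:
    """Bounded nonlinear least squares of f(t) = A (1 - exp(-k t)).

    Initialisation: A0 = min(1, 1.05 * max f); k0 from the log-linear
    slope of the first two points under A0. Bounds A in [0, 1], k >= 0.
    A constant-zero course returns A = 0 with ``k_identifiable=False``.
    """
    t = np.asarray(tc.timepoints, float)
    f = np.asarray(tc.values, float)
    mask = np.isfinite(f)
    t, f = t[mask], f[mask]
    if t.size < 3:
        raise ValueError("need >= 3 timepoints for the saturating fit")
    if np.max(f) <= 0.0:
        return SaturatingFit(A=0.0, k=0.0, rss=float(np.sum(f**2)), k_identifiable=False)

    A0 = min(1.0, 1.05 * float(np.max(f)))
    # slope of ln(1 - f/A0) over the first two informative points
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.log(np.clip(1.0 - f / A0, 1e-9, None))
    dt = t[1] - t[0] if t[1] > t[0] else 1.0
    k0 = max(1e-6, -(z[1] - z[0]) / dt)

    def model(tt, A, k):
        return A * (1.0 - np.exp(-k * tt))

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            f,
            p0=[A0, k0],
            bounds=([0.0, 0.0], [1.0, np.inf]),
            ftol=1e-8,
            xtol=1e-12,
            maxfev=max_iter,
        )
    except RuntimeError as err:
        raise RuntimeError(f"saturating fit did not converge: {err}") from err
    A, k = float(popt[0]), float(popt[1])
    rss = float(np.sum((f - model(t, A, k)) ** 2))
    return SaturatingFit(A=A, k=k, rss=rss)


def relative_rate(fit: KineticFit, reference: KineticFit) -> RelativeRate:
    """Rate of a subset divided by the reference (genome-wide) rate."""
    if reference.k == 0:
        raise ValueError("reference rate is zero; relative rate undefined")
    return RelativeRate(r=fit.k / reference.k)
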