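"""Dual-isotope regime diagnostics for pore-water nitrate profiles.

The inference logic: regress d18O on d15N of pore-water nitrate, locate the
depth at which the relationship changes (two-segment least squares over
candidate break depths), estimate apparent Rayleigh fractionations from
delta-vs-log-concentration slopes, and classify each interval.  A
dual-isotope slope indistinguishable from 1 is the fingerprint of
denitrification alone (equal 15N and 18O enrichment by respiratory nitrate
reductase); a slope significantly above 1 requires an additional nitrate
source whose d15N and d18O are set independently -- nitrification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .profile import PorewaterProfile

__all__ = [
    "OLSResult",
    "SegmentedFit",
    "ols_fit",
    "segmented_fit",
    "apparent_epsilon",
    "classify_regime",
    "REGIME_DENITRIFICATION",
    "REGIME_COUPLED",
    "REGIME_INDETERMINATE",
]

REGIME_DENITRIFICATION = "denitrification-only"
REGIME_COUPLED = "coupled nitrification-denitrification"
REGIME_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class OLSResult:
    slope: float
    intercept: float
    se_slope: float
    rss: float
    n: int


@dataclass(frozen=True)
class SegmentedFit:
    """Result of a two-segment d18O-vs-d15N regression split by depth."""

    break_depth: float
    slope_upper: float
    slope_lower: float
    se_upper: float
    se_lower: float
    intercept_upper: float
    intercept_lower: float
    rss_total: float
    n_upper: int
    n_lower: int


def ols_fit(x, y) -> OLSResult:
    """Ordinary least squares of ``y`` on ``x`` with the classical slope s.e.

    Requires at least three points and non-degenerate ``x``.  For exactly
    collinear data the standard error is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"at least 3 points required, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; slope is undefined")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    rss = float(resid @ resid)
    se = 0.0 if res.stderr is None else float(res.stderr)
    # linregress returns nan stderr for perfectly collinear input on some
    # platforms; normalize to 0.
    if not np.isfinite(se):
        se = 0.0
    return OLSResult(float(res.slope), float(res.intercept), se, rss, int(x.size))


def default_candidate_breaks(depths: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive observed depths."""
    d = np.unique(np.asarray(depths, dtype=float))
    return (d[1:] + d[:-1]) / 2.0


def segmented_fit(
    profile: PorewaterProfile,
    candidate_breaks=None,
    min_points: int = 3,
) -> SegmentedFit:
    """Two-segment d18O-vs-d15N regression over candidate break depths.

    Rows without isotope values (nitrate below the reporting threshold) are
    excluded.  For each candidate break, independent OLS fits are made for
    samples shallower than the break and at-or-below it; the break
    minimizing the total residual sum of squares wins, ties going to the
    shallowest candidate.
    """
    mask = profile.isotope_mask
    depth = profile.depth[mask]
    x = profile.d15n[mask]
    y = profile.d18o[mask]
    if candidate_breaks is None:
        candidate_breaks = default_candidate_breaks(depth)
    candidate_breaks = np.sort(np.asarray(candidate_breaks, dtype=float))
    best: SegmentedFit | None = None
    for b in candidate_breaks:
        upper = depth < b
        lower = ~upper
        if upper.sum() < min_points or lower.sum() < min_points:
            continue
        try:
            fu = ols_fit(x[upper], y[upper])
            fl = ols_fit(x[lower], y[lower])
        except ValueError:
            continue
        rss = fu.rss + fl.rss
        # a candidate must beat the incumbent by more than float jitter,
        # so exact ties resolve to the shallowest break
        improves = best is not None and best.rss_total - rss > 1e-9 * max(1.0, best.rss_total)
        if best is None or improves:
            best = SegmentedFit(
                break_depth=float(b),
                slope_upper=fu.slope,
                slope_lower=fl.slope,
                se_upper=fu.se_slope,
                se_lower=fl.se_slope,
                intercept_upper=fu.intercept,
                intercept_lower=fl.intercept,
                rss_total=rss,
                n_upper=fu.n,
                n_lower=fl.n,
            )
    if best is None:
        raise ValueError(
            "no feasible break: not enough isotope-bearing rows for two "
            f"segments of {min_points} points"
        )
    return best


def apparent_epsilon(conc, delta, c_ref: float) -> float:
    """Apparent Rayleigh fractionation from a delta-vs-concentration profile.

    OLS slope of ``delta`` on ``-ln(conc / c_ref)``; on linear-form
    closed-system Rayleigh data this recovers epsilon exactly, and it is
    invariant to rescaling all concentrations together with ``c_ref``.
    """
    conc = np.asarray(conc, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if not c_ref > 0:
        raise ValueError("c_ref must be positive")
    xs = -np.log(conc / c_ref)
    return ols_fit(xs, delta).slope


def classify_regime(slope: float, se: float, tau: float = 0.25) -> str:
    """Label a depth interval from its dual-isotope slope.

    ``denitrification-only`` when the slope is within ``max(tau, 2*se)`` of
    1, ``coupled nitrification-denitrification`` when significantly above
    1, ``indeterminate`` when significantly below 1.
    """
    if se < 0:
        raise ValueError("se must be non-negative")
    if not tau > 0:
        raise ValueError("tau must be positive")
    band = max(tau, 2.0 * se)
    if abs(slope - 1.0) <= band:
        return REGIME_DENITRIFICATION
    if slope - 1.0 > band:
        return REGIME_COUPLED
    return REGIME_INDETERMINATE
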