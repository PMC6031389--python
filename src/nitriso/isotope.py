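"""Delta-notation arithmetic, closed-system Rayleigh fractionation and pool mixing.

Isotope compositions are carried as per-mil (permil) delta values,

    delta = (R_sample / R_standard - 1) * 1000,

where ``R`` is a heavy/light isotope ratio.  A kinetic fractionation
``epsilon`` is positive when the *residual* substrate pool becomes
isotopically heavier as it is consumed (the usual convention for
respiratory O2 consumption and dissimilatory nitrate reduction).

Two evaluation forms of the closed-system Rayleigh distillation are
provided:

``exact``
    ratio-space power law, ``R = R0 * f**(-epsilon/1000)``, equivalently
    ``delta = (delta0 + 1000) * f**(-epsilon/1000) - 1000``;
``linear``
    the first-order approximation ``delta = delta0 - epsilon * ln(f)``
    that most field studies quote.

Both are retained because published worked values are frequently computed
with the linear form while mass-balance checks require the exact form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "STANDARD_RATIOS",
    "DeltaValue",
    "RayleighParams",
    "delta_from_ratio",
    "ratio_from_delta",
    "rayleigh_residual",
    "rayleigh_accumulated_product",
    "mix_pools",
    "denitrification_trajectory",
]

RayleighForm = Literal["exact", "linear"]

#: Absolute isotope ratios of the international reference standards.
#: 15N/14N of atmospheric N2, 18O/16O of V-SMOW, 13C/12C of V-PDB.
STANDARD_RATIOS: dict[str, float] = {
    "AIR": 0.0036765,
    "V-SMOW": 0.0020052,
    "V-PDB": 0.0111802,
}


@dataclass(frozen=True)
class DeltaValue:
    """An isotope composition in per-mil relative to a named standard.

    Parameters
    ----------
    value:
        Per-mil deviation from the reference standard.  Must exceed
        -1000 permil (an isotope ratio cannot be negative).
    standard:
        Reference-standard label; one of ``AIR``, ``V-SMOW``, ``V-PDB``.
    """

    value: float
    standard: str = "V-SMOW"

    def __post_init__(self) -> None:
        if self.standard not in STANDARD_RATIOS:
            raise ValueError(
                f"unknown reference standard {self.standard!r}; "
                f"expected one of {sorted(STANDARD_RATIOS)}"
            )
        if not self.value > -1000.0:
            raise ValueError(
                f"delta value {self.value} permil implies a non-positive isotope ratio"
            )

    @property
    def ratio(self) -> float:
        """Absolute isotope ratio implied by this delta value."""
        return ratio_from_delta(self.value, STANDARD_RATIOS[self.standard])

    @classmethod
    def from_ratio(cls, r_sample: float, standard: str) -> "DeltaValue":
        return cls(delta_from_ratio(r_sample, STANDARD_RATIOS[standard]), standard)


@dataclass(frozen=True)
class RayleighParams:
    """Parameters of a closed-system Rayleigh distillation.

    ``epsilon`` is the kinetic fractionation in per-mil, positive when the
    residual substrate is enriched.  ``form`` selects the exact ratio-space
    power law (default) or the linear log approximation.
    """

    delta0: float
    epsilon: float
    form: RayleighForm = "exact"

    def __post_init__(self) -> None:
        if not math.isfinite(self.epsilon) or abs(self.epsilon) >= 1000.0:
            raise ValueError(f"epsilon must be finite with |epsilon| < 1000, got {self.epsilon}")
        if not self.delta0 > -1000.0:
            raise ValueError(f"delta0 must exceed -1000 permil, got {self.delta0}")
        if self.form not in ("exact", "linear"):
            raise ValueError(f"form must be 'exact' or 'linear', got {self.form!r}")


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Per-mil delta value of a sample ratio against a standard ratio."""
    if not r_sample > 0:
        raise ValueError(f"r_sample must be positive, got {r_sample}")
    if not r_standard > 0:
        raise ValueError(f"r_standard must be positive, got {r_standard}")
    return (r_sample / r_standard - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Absolute isotope ratio implied by a per-mil delta value."""
    if not delta > -1000.0:
        raise ValueError(f"delta must exceed -1000 permil, got {delta}")
    if not r_standard > 0:
        raise ValueError(f"r_standard must be positive, got {r_standard}")
    return r_standard * (1.0 + delta / 1000.0)


def _check_f(f, *, closed_top: bool = True) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("fraction remaining f must be > 0")
    if closed_top:
        if np.any(f > 1):
            raise ValueError("fraction remaining f must be <= 1")
    else:
        if np.any(f >= 1):
            raise ValueError("fraction remaining f must be < 1")
    return f


def rayleigh_residual(params: RayleighParams, f) -> float | np.ndarray:
    """Composition of the residual substrate after a fraction ``1 - f`` is consumed.

    ``f`` is the fraction of the initial substrate remaining, in (0, 1].
    Scalar or array-like ``f`` is accepted; the return mirrors the input
    shape.  At ``f = 1`` both forms return ``delta0``.
    """
    f = _check_f(f)
    if params.form == "exact":
        out = (params.delta0 + 1000.0) * f ** (-params.epsilon / 1000.0) - 1000.0
    else:
        out = params.delta0 - params.epsilon * np.log(f)
    return float(out) if out.ndim == 0 else out


def rayleigh_accumulated_product(params: RayleighParams, f) -> float | np.ndarray:
    """Composition of the pooled (accumulated) product at fraction remaining ``f``.

    Defined by isotope mass balance against the residual substrate.  In the
    exact form the balance is closed in ratio space,

        R0 = f * R_residual + (1 - f) * R_product,

    so that substrate and accumulated product always recombine to the
    initial composition.  In the linear form the balance is closed in delta
    space, which reproduces the textbook limit
    ``delta_product -> delta0 - epsilon`` as ``f -> 1``.
    """
    f = _check_f(f, closed_top=False)
    residual = rayleigh_residual(params, f)
    if params.form == "exact":
        out = ((params.delta0 + 1000.0) - f * (np.asarray(residual) + 1000.0)) / (1.0 - f) - 1000.0
    else:
        out = (params.delta0 - f * np.asarray(residual)) / (1.0 - f)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def mix_pools(
    pools: Iterable[tuple[float, float]],
    *,
    ratio_space: bool = False,
    r_standard: float = STANDARD_RATIOS["V-SMOW"],
) -> float:
    """Isotope composition of a mixture of pools.

    ``pools`` is an iterable of ``(concentration, delta)`` pairs.  The
    default is the delta-linear convention (concentration-weighted mean of
    per-mil values), which is exact for ratio-space balances of the form
    ``sum(c_i * R_i)`` because ``R`` is affine in delta.  With
    ``ratio_space=True`` the mixture is computed by explicit heavy/light
    atom bookkeeping at the given standard ratio; for natural-abundance
    ratios the two conventions differ by far less than 0.1 permil.
    """
    pools = list(pools)
    if not pools:
        raise ValueError("at least one pool is required")
    conc = np.array([c for c, _ in pools], dtype=float)
    delta = np.array([d for _, d in pools], dtype=float)
    if np.any(conc < 0):
        raise ValueError("pool concentrations must be non-negative")
    total = conc.sum()
    if not total > 0:
        raise ValueError("at least one pool concentration must be positive")
    if not ratio_space:
        return float(np.dot(conc, delta) / total)
    ratios = r_standard * (1.0 + delta / 1000.0)
    heavy = conc * ratios / (1.0 + ratios)
    light = conc / (1.0 + ratios)
    return delta_from_ratio(heavy.sum() / light.sum(), r_standard)


def denitrification_trajectory(
    delta15_0: float,
    delta18_0: float,
    eps15: float,
    eps18: float,
    f_grid: Sequence[float],
    form: RayleighForm = "exact",
) -> np.ndarray:
    """Dual-isotope trajectory of residual nitrate during closed-system reduction.

    Returns an ``(n, 2)`` array of ``(d15N, d18O)`` pairs of the residual
    nitrate pool evaluated on ``f_grid`` (fractions remaining, strictly
    decreasing, in (0, 1]).  With equal fractionations and the linear form
    the points fall exactly on a line of slope 1; with the exact form the
    slope is ``(delta18_0 + 1000) / (delta15_0 + 1000)``.
    """
    f = np.asarray(f_grid, dtype=float)
    if f.size == 0:
        raise ValueError("f_grid must contain at least one fraction")
    if np.any(np.diff(f) >= 0):
        if f.size > 1:
            raise ValueError("f_grid must be strictly decreasing")
    _check_f(f)
    d15 = rayleigh_residual(RayleighParams(delta15_0, eps15, form), f)
    d18 = rayleigh_residual(RayleighParams(delta18_0, eps18, form), f)
    return np.column_stack([np.atleast_1d(d15), np.atleast_1d(d18)])
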