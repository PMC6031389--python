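"""The nitrification oxygen-isotope endmember model.

Newly nitrified nitrate acquires its oxygen from ambient water and
dissolved O2 during the two-step oxidation of ammonium (ammonia oxidizers
produce nitrite; nitrite-oxidizing bacteria, NOB, produce nitrate).  When
the intermediate nitrite pool does not accumulate, the d18O of the nitrate
produced (``d18O_NTR``) is

    d18O_NTR = (1 - X_NOB) * (2/3 * d18O_NO2pro + 1/3 * (d18O_H2O - eps_k_H2O_NOB))
               + X_NOB * (d18O_H2O + eps_eq)

with the d18O of nitrite produced by ammonia oxidation

    d18O_NO2pro = 0.5 * (1 + X_AO) * d18O_H2O
                  + 0.5 * (1 - X_AO) * (d18O_O2 - eps_k_O2_AO - eps_k_H2O_AO)
                  + X_AO * eps_eq.

``X_AO`` and ``X_NOB`` are the fractions of nitrite oxygen atoms that have
equilibrated with water during ammonia oxidation and nitrite oxidation;
``eps_eq`` is the nitrite-water equilibrium fractionation (15 permil at
4 C); the ``eps_k`` terms are kinetic fractionations for oxygen-atom
incorporation.  The nitrogen endmember of nitrification tracks the d15N of
the ambient organic matter within about +/-1 permil, because remineralized
ammonium inherits the host organic matter's d15N and is quantitatively
consumed when neither ammonium nor nitrite accumulates.

Dissolved O2 itself grows isotopically heavier downward as aerobic
respiration (eps ~ 20 permil) consumes it, which propagates into a
downward increase of ``d18O_NTR``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping, NamedTuple

import numpy as np

from .isotope import RayleighForm, RayleighParams, rayleigh_residual

__all__ = [
    "X_AO_PLAUSIBLE",
    "EPS_SUM_AO_PLAUSIBLE",
    "NitrificationParams",
    "O2State",
    "delta18o_nitrite_produced",
    "delta18o_nitrification",
    "delta18o_o2_at_depth",
    "delta15n_nitrification",
    "endmember_uncertainty",
    "EndmemberPercentiles",
]

#: Plausible range of the water-equilibrated oxygen fraction during ammonia
#: oxidation, from culture experiments with ammonia-oxidizing archaea and
#: bacteria.
X_AO_PLAUSIBLE: tuple[float, float] = (0.10, 0.25)

#: Plausible range of the combined kinetic fractionation
#: eps_k_O2_AO + eps_k_H2O_AO (permil).  Together with ``X_AO_PLAUSIBLE``
#: this range maps, through the produced-nitrite equation at
#: d18O_O2 = 27 permil, onto produced-nitrite compositions spanning
#: -1 to +7 permil.
EPS_SUM_AO_PLAUSIBLE: tuple[float, float] = (18.33, 32.56)


@dataclass(frozen=True)
class NitrificationParams:
    """Parameters of the two-step nitrification oxygen-isotope model.

    ``x_ao`` and ``eps_sum_ao`` have no consensus single value and must be
    supplied explicitly (see :data:`X_AO_PLAUSIBLE` and
    :data:`EPS_SUM_AO_PLAUSIBLE`); :meth:`typical` builds a parameter set at
    the midpoints of those documented ranges.  The remaining defaults are
    the experimental values for NOB equilibration (``x_nob = 0.02``), the
    NOB water-incorporation kinetic fractionation (15 permil), the
    nitrite-water equilibrium fractionation at 4 C (15 permil), seawater
    d18O (0 permil V-SMOW) and an organic-matter d15N of 11 permil (AIR).
    """

    x_ao: float
    eps_sum_ao: float
    x_nob: float = 0.02
    eps_k_h2o_nob: float = 15.0
    eps_eq: float = 15.0
    delta18o_h2o: float = 0.0
    delta15n_om: float = 11.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_ao <= 1.0:
            raise ValueError(f"x_ao must lie in [0, 1], got {self.x_ao}")
        if not 0.0 <= self.x_nob <= 1.0:
            raise ValueError(f"x_nob must lie in [0, 1], got {self.x_nob}")

    @classmethod
    def typical(cls, **overrides) -> "NitrificationParams":
        """Parameter set at the midpoints of the documented plausible ranges."""
        params = cls(
            x_ao=0.5 * (X_AO_PLAUSIBLE[0] + X_AO_PLAUSIBLE[1]),
            eps_sum_ao=0.5 * (EPS_SUM_AO_PLAUSIBLE[0] + EPS_SUM_AO_PLAUSIBLE[1]),
        )
        return replace(params, **overrides) if overrides else params


@dataclass(frozen=True)
class O2State:
    """Dissolved-O2 state used to drive the endmember's depth dependence.

    ``delta18o_o2`` is the bottom-water composition (27 permil V-SMOW is
    the deep-ocean value implied by ~170 umol O2 / kg), ``f_o2`` the
    fraction of bottom-water O2 remaining, and ``eps_resp`` the aerobic
    respiration fractionation (20 +/- 3 permil).
    """

    f_o2: float = 1.0
    delta18o_o2: float = 27.0
    eps_resp: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 < self.f_o2 <= 1.0:
            raise ValueError(f"f_o2 must lie in (0, 1], got {self.f_o2}")


def delta18o_nitrite_produced(params: NitrificationParams, delta18o_o2) -> float | np.ndarray:
    """d18O of nitrite produced by ammonia oxidation at the given d18O_O2."""
    x = params.x_ao
    d = np.asarray(delta18o_o2, dtype=float)
    out = (
        0.5 * (1.0 + x) * params.delta18o_h2o
        + 0.5 * (1.0 - x) * (d - params.eps_sum_ao)
        + x * params.eps_eq
    )
    return float(out) if out.ndim == 0 else out


def delta18o_nitrification(params: NitrificationParams, delta18o_no2_pro) -> float | np.ndarray:
    """d18O of nitrate produced by full nitrification (non-accumulating nitrite)."""
    xn = params.x_nob
    d = np.asarray(delta18o_no2_pro, dtype=float)
    out = (1.0 - xn) * (
        2.0 / 3.0 * d + 1.0 / 3.0 * (params.delta18o_h2o - params.eps_k_h2o_nob)
    ) + xn * (params.delta18o_h2o + params.eps_eq)
    return float(out) if out.ndim == 0 else out


def delta18o_o2_at_depth(state: O2State, form: RayleighForm = "exact") -> float:
    """d18O of residual dissolved O2 after respiratory drawdown to ``f_o2``."""
    return float(
        rayleigh_residual(
            RayleighParams(state.delta18o_o2, state.eps_resp, form), state.f_o2
        )
    )


def delta15n_nitrification(params: NitrificationParams) -> tuple[float, float]:
    """Nitrogen endmember of nitrification: (central d15N, half-width).

    The d15N of nitrified nitrate equals the ambient organic-matter d15N
    within about +/-1 permil, since remineralized ammonium carries the host
    organic matter's nitrogen isotope composition.
    """
    return (params.delta15n_om, 1.0)


class EndmemberPercentiles(NamedTuple):
    p2_5: float
    p50: float
    p97_5: float


# Monte-Carlo draws consume uncertain parameters in this fixed order so that
# results are reproducible for a given seed regardless of mapping order.
_SAMPLED_FIELDS = tuple(f.name for f in fields(NitrificationParams))


def endmember_uncertainty(
    base: NitrificationParams,
    param_ranges: Mapping[str, tuple[float, float]],
    delta18o_o2: float,
    n_draws: int = 10_000,
    seed: int = 0,
) -> EndmemberPercentiles:
    """Propagate parameter ranges through the endmember model by Monte Carlo.

    Each named parameter is drawn independently and uniformly over its
    ``(low, high)`` range (the literature supplies ranges, not
    distributions); unnamed parameters stay at their ``base`` values.
    Returns the 2.5th, 50th and 97.5th percentiles of ``d18O_NTR``.
    Identical seeds give identical output.
    """
    if n_draws < 100:
        raise ValueError(f"n_draws must be at least 100, got {n_draws}")
    for name, (low, high) in param_ranges.items():
        if name not in _SAMPLED_FIELDS:
            raise ValueError(f"unknown nitrification parameter {name!r}")
        if low > high:
            raise ValueError(f"invalid range for {name!r}: low {low} > high {high}")
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for name in _SAMPLED_FIELDS:
        if name in param_ranges:
            low, high = param_ranges[name]
            draws[name] = rng.uniform(low, high, size=n_draws)
        else:
            draws[name] = np.full(n_draws, getattr(base, name))
    # Evaluate the two-equation chain vectorized over draws.
    x_ao = draws["x_ao"]
    no2_pro = (
        0.5 * (1.0 + x_ao) * draws["delta18o_h2o"]
        + 0.5 * (1.0 - x_ao) * (delta18o_o2 - draws["eps_sum_ao"])
        + x_ao * draws["eps_eq"]
    )
    xn = draws["x_nob"]
    ntr = (1.0 - xn) * (
        2.0 / 3.0 * no2_pro + 1.0 / 3.0 * (draws["delta18o_h2o"] - draws["eps_k_h2o_nob"])
    ) + xn * (draws["delta18o_h2o"] + draws["eps_eq"])
    p = np.percentile(ntr, [2.5, 50.0, 97.5])
    return EndmemberPercentiles(float(p[0]), float(p[1]), float(p[2]))
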