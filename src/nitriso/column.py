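"""Synthetic pore-water column generator.

A steady-state, sequential-cell forward model of a diagenetic nitrate
column.  Working downward from bottom water, each cell

1. experiences an imposed exponential O2 drawdown, which sets the local
   d18O of dissolved O2 by Rayleigh fractionation (aerobic respiration);
2. loses a per-cell fraction of its nitrate to denitrification, enriching
   the residual pool in 15N and 18O with equal fractionations;
3. above the regime-break depth, gains newly nitrified nitrate whose d15N
   is the organic-matter value and whose d18O is the nitrification
   endmember evaluated at the local d18O_O2 (rising downward as O2 is
   consumed);
4. carries simple stoichiometric bookkeeping for NH4, NO2, PO4 and
   alkalinity (remineralization releases PO4 and alkalinity, nitrification
   consumes ammonium, a small fraction of denitrified N transits the
   nitrite pool).

There is no explicit diffusion or advection: the generator reproduces the
endmember/Rayleigh statistical structure that the dual-isotope diagnostics
assume, not a reaction-transport solution.  Below the break depth
nitrification is off and the column follows a pure closed-system
denitrification trajectory (dual-isotope slope ~ 1).

Default rates are synthetic: they are chosen so that the noise-free column
reproduces the qualitative hadal-sediment profile shape (bottom-water
nitrate near 36 uM drawn below 5 uM by ~85 cmbsf, nitrate d15N rising from
4.4 toward ~18 permil and d18O from 2.8 toward ~21 permil, a steep
dual-isotope slope above the 50-cmbsf break and a slope near 1 below it);
they are not inferred rate constants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .isotope import RayleighForm, RayleighParams, mix_pools, rayleigh_residual
from .nitrification import (
    NitrificationParams,
    O2State,
    delta15n_nitrification,
    delta18o_nitrification,
    delta18o_nitrite_produced,
    delta18o_o2_at_depth,
)
from .profile import PorewaterProfile

__all__ = ["ColumnConfig", "ConfigError", "simulate_column", "add_measurement_noise"]


class ConfigError(ValueError):
    """A column configuration violates its invariants."""


#: Default cell-midpoint grid (cmbsf): 5-cm sampling above 20 cmbsf and
#: 10-cm sampling below, ending where nitrate approaches depletion.
DEFAULT_DEPTHS: tuple[float, ...] = (2.5, 7.5, 12.5, 17.5, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 85.0)

#: Default per-cell denitrification fractions: weak in the oxygenated
#: shallow interval, increasing toward the break as O2 wanes, and strong
#: below it (fully anoxic denitrification).  Together with the default
#: additions these draw nitrate from 36 uM down through ~22 uM at the
#: break to under 5 uM by 85 cmbsf.
DEFAULT_DENIT_FRAC: tuple[float, ...] = (
    0.036, 0.037, 0.050, 0.076, 0.181, 0.291, 0.364,
    0.36, 0.36, 0.36, 0.36,
)

#: Default per-cell nitrified-nitrate additions (uM), mirroring nitrifier
#: abundance maxima near the base of the oxic interval (~45 cmbsf), zero
#: below the break.
DEFAULT_NTR_ADD: tuple[float, ...] = (
    0.3, 0.3, 0.7, 1.0, 2.7, 4.8, 6.1,
    0.0, 0.0, 0.0, 0.0,
)


@dataclass(frozen=True)
class ColumnConfig:
    """Full parameterization of the synthetic pore-water column."""

    depths: tuple[float, ...] = DEFAULT_DEPTHS
    no3_bw: float = 36.0           # bottom-water nitrate, uM
    d15n_bw: float = 4.4           # bottom-water nitrate d15N, permil AIR
    d18o_bw: float = 2.8           # bottom-water nitrate d18O, permil V-SMOW
    o2_bw: float = 170.0           # bottom-water O2, umol/kg (context only)
    d18o_o2_bw: float = 27.0       # bottom-water dissolved-O2 d18O, permil
    eps_resp: float = 20.0         # aerobic-respiration fractionation, permil
    o2_efold: float = 7.5          # e-folding depth of O2 consumption, cm
    break_depth: float = 50.0      # regime boundary, cmbsf
    denit_frac: float | tuple[float, ...] = DEFAULT_DENIT_FRAC
    ntr_add: float | tuple[float, ...] = DEFAULT_NTR_ADD
    # expressed (sediment-scale apparent) fractionations of denitrification;
    # equal 15N and 18O values give the slope-1 deep fingerprint
    eps15_denit: float = 3.0
    eps18_denit: float = 3.0
    form: RayleighForm = "exact"
    nitrification: NitrificationParams = field(default_factory=NitrificationParams.typical)
    # bottom-water values of the bookkeeping solutes
    no2_bw: float = 0.05           # uM
    nh4_bw: float = 0.5            # uM
    po4_bw: float = 2.5            # uM
    alkalinity_bw: float = 2.4     # mM
    # stoichiometric bookkeeping
    remin_n_to_p: float = 16.0     # Redfield N:P of remineralized organic matter
    alk_per_n: float = 1.0         # meq alkalinity per mmol N denitrified
    no2_leak_frac: float = 0.06    # fraction of denitrified N transiting NO2
    # measurement noise and reporting
    noise_iso: float = 0.2         # permil, s.d. on both isotope columns
    noise_conc: float = 0.02       # relative s.d. on concentrations
    iso_threshold: float = 0.5     # uM nitrate below which isotopes are not reported
    seed: int = 0

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        if depths.size < 2 or np.any(np.diff(depths) <= 0):
            raise ConfigError("depths must be a strictly increasing grid with >= 2 cells")
        for name in ("no3_bw", "noise_iso", "noise_conc", "iso_threshold"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        g = self.denit_frac_per_cell()
        if np.any(g < 0) or np.any(g >= 1):
            raise ConfigError("denit_frac must lie in [0, 1) for every cell")
        a = self.ntr_add_per_cell()
        if np.any(a < 0):
            raise ConfigError("ntr_add must be non-negative")
        below = depths >= self.break_depth
        if np.any(a[below] > 0):
            idx = int(np.flatnonzero(below & (a > 0))[0])
            raise ConfigError(
                f"ntr_add must be zero below break_depth; cell {idx} at "
                f"{depths[idx]} cmbsf has ntr_add={a[idx]}"
            )

    def _per_cell(self, value, name: str) -> np.ndarray:
        n = len(self.depths)
        if np.isscalar(value):
            out = np.full(n, float(value))
            if name == "ntr_add":
                out[np.asarray(self.depths) >= self.break_depth] = 0.0
            return out
        arr = np.asarray(value, dtype=float)
        if arr.shape != (n,):
            raise ConfigError(f"{name} must be scalar or one value per cell ({n}), got {arr.shape}")
        return arr

    def denit_frac_per_cell(self) -> np.ndarray:
        return self._per_cell(self.denit_frac, "denit_frac")

    def ntr_add_per_cell(self) -> np.ndarray:
        """Per-cell nitrified additions; a scalar applies only above break_depth."""
        return self._per_cell(self.ntr_add, "ntr_add")

    def digest(self) -> str:
        """Short stable hash of the full configuration, for run provenance."""
        payload = asdict(self)
        payload["depths"] = list(map(float, self.depths))
        for key in ("denit_frac", "ntr_add"):
            v = payload[key]
            payload[key] = list(map(float, v)) if not np.isscalar(v) else float(v)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def simulate_column(config: ColumnConfig) -> PorewaterProfile:
    """Run the sequential-cell forward model; returns the noise-free profile."""
    depths = np.asarray(config.depths, dtype=float)
    g = config.denit_frac_per_cell()
    a = config.ntr_add_per_cell()
    d15n_add, _half = delta15n_nitrification(config.nitrification)

    n_cells = depths.size
    no3 = np.empty(n_cells)
    d15 = np.empty(n_cells)
    d18 = np.empty(n_cells)
    no2 = np.empty(n_cells)
    nh4 = np.empty(n_cells)
    po4 = np.empty(n_cells)
    alk = np.empty(n_cells)

    pool_n, pool_15, pool_18 = config.no3_bw, config.d15n_bw, config.d18o_bw
    nh4_c, po4_c, alk_c = config.nh4_bw, config.po4_bw, config.alkalinity_bw

    for i, z in enumerate(depths):
        f_o2 = float(np.exp(-z / config.o2_efold))
        d18o_o2 = delta18o_o2_at_depth(
            O2State(f_o2=f_o2, delta18o_o2=config.d18o_o2_bw, eps_resp=config.eps_resp),
            form=config.form,
        )
        # (2) closed-system denitrification of a fraction g[i] of the pool
        removed = pool_n * g[i]
        if g[i] > 0:
            f_cell = 1.0 - g[i]
            pool_15 = float(
                rayleigh_residual(RayleighParams(pool_15, config.eps15_denit, config.form), f_cell)
            )
            pool_18 = float(
                rayleigh_residual(RayleighParams(pool_18, config.eps18_denit, config.form), f_cell)
            )
            pool_n -= removed
        if pool_n < 0:
            raise ConfigError(f"nitrate pool driven below zero in cell {i} at {z} cmbsf")
        # (3) nitrified addition above the break
        if a[i] > 0:
            ntr_18 = delta18o_nitrification(
                config.nitrification,
                delta18o_nitrite_produced(config.nitrification, d18o_o2),
            )
            pool_15 = mix_pools([(pool_n, pool_15), (a[i], d15n_add)])
            pool_18 = mix_pools([(pool_n, pool_18), (a[i], ntr_18)])
            pool_n += a[i]
        # (4) stoichiometric bookkeeping: remineralization (aerobic where
        # nitrification runs, anaerobic via denitrification) releases PO4 and
        # alkalinity; nitrification consumes the ammonium it nitrifies.
        remin_n = removed + a[i]
        nh4_c = max(nh4_c + remin_n - a[i] - removed, 0.0)
        po4_c += remin_n / config.remin_n_to_p
        alk_c += config.alk_per_n * removed / 1000.0
        no3[i] = pool_n
        d15[i] = pool_15
        d18[i] = pool_18
        no2[i] = config.no2_bw + config.no2_leak_frac * removed
        nh4[i] = nh4_c
        po4[i] = po4_c
        alk[i] = alk_c

    profile = PorewaterProfile.from_columns(
        {
            "depth_cmbsf": depths,
            "no3_uM": no3,
            "no2_uM": no2,
            "nh4_uM": nh4,
            "po4_uM": po4,
            "alkalinity_mM": alk,
            "d15n_no3_permil": d15,
            "d18o_no3_permil": d18,
        }
    )
    return profile.apply_reporting_threshold(config.iso_threshold)


_NOISE_CONC_COLUMNS = ("no3_uM", "no2_uM", "nh4_uM", "po4_uM", "alkalinity_mM")


def add_measurement_noise(
    profile: PorewaterProfile,
    noise_iso: float = 0.2,
    noise_conc: float = 0.02,
    seed: int = 0,
) -> PorewaterProfile:
    """Add Gaussian measurement noise to a profile.

    Independent draws: s.d. ``noise_iso`` (permil) on both isotope columns,
    relative s.d. ``noise_conc`` on every concentration column (clamped at
    zero).  Draws are consumed column-major -- all d15N, then all d18O,
    then the concentration columns in canonical order -- so adding columns
    never perturbs earlier draws.  Same seed, same output.
    """
    if noise_iso < 0 or noise_conc < 0:
        raise ValueError("noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    df = profile.data.copy()
    n = len(df)
    for col in ("d15n_no3_permil", "d18o_no3_permil"):
        draws = rng.normal(0.0, 1.0, size=n)
        vals = df[col].to_numpy()
        finite = np.isfinite(vals)
        df.loc[finite, col] = vals[finite] + noise_iso * draws[finite]
    for col in _NOISE_CONC_COLUMNS:
        draws = rng.normal(0.0, 1.0, size=n)
        vals = df[col].to_numpy()
        finite = np.isfinite(vals)
        df.loc[finite, col] = np.maximum(vals[finite] * (1.0 + noise_conc * draws[finite]), 0.0)
    return PorewaterProfile(df)
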