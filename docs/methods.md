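# Methods

## Delta notation and conventions

Isotope compositions are per-mil deviations, δ = (R_sam/R_std − 1)×1000,
with δ¹⁵N against atmospheric N₂ (AIR), δ¹⁸O against V-SMOW and δ¹³C
against V-PDB. All internal arithmetic is double precision; values are
rounded (6 significant digits) only at table output.

A fractionation ε is positive when the **residual substrate** pool grows
heavier as it is consumed. This matches how respiration and
denitrification fractionations are quoted in the field, and lets every
literature value enter the configuration as a positive number.

## Closed-system Rayleigh fractionation

Two evaluation forms are carried throughout:

- exact (ratio space): δ = (δ₀ + 1000)·f^(−ε/1000) − 1000,
- linear: δ = δ₀ − ε·ln f,

where f is the fraction of substrate remaining. The exact form is the
default because it closes the isotope mass balance to machine precision;
the linear form is retained because field worked values are usually
computed with it. The two differ by δ₀·εL/1000 + (εL)²/2000 + O(x³) with
L = −ln f, i.e. by < 0.1‰ when εL < 5‰ and |δ₀| ≲ 15‰. At the benchmark
scenario of 88% O₂ consumption (δ₀ = 27‰, ε = 20‰, f = 0.12) the forms
give 69.4‰ and 71.5‰, bracketing the conventional "≈70‰" figure; any
check against that figure must therefore allow ±2.5‰.

The accumulated (pooled) product is defined by mass balance against the
residual: in ratio space for the exact form
(R₀ = f·R_res + (1−f)·R_prod), in delta space for the linear form, which
reproduces the textbook onset limit δ_prod → δ₀ − ε as f → 1.

Pool mixing is concentration-weighted in delta space. Because R is affine
in δ, this is *identical* to a ratio-space balance of the form Σcᵢ·Rᵢ; an
explicit heavy/light-atom bookkeeping alternative (`ratio_space=True`)
differs by ≪ 0.1‰ at natural abundance and is provided for verification.

## The nitrification δ¹⁸O endmember

When neither ammonium nor nitrite accumulates, nitrate produced by the
two-step oxidation of ammonia has

    δ¹⁸O_NO2,pro = ½(1+X_AO)·δ¹⁸O_H2O + ½(1−X_AO)·(δ¹⁸O_O2 − ¹⁸ε_k,O2,AO − ¹⁸ε_k,H2O,AO) + X_AO·¹⁸ε_eq
    δ¹⁸O_NTR    = (1−X_NOB)·(⅔·δ¹⁸O_NO2,pro + ⅓·(δ¹⁸O_H2O − ¹⁸ε_k,H2O,NOB)) + X_NOB·(δ¹⁸O_H2O + ¹⁸ε_eq)

Parameter defaults (all overridable):

| parameter | default | units | provenance |
|---|---|---|---|
| X_NOB | 0.02 | – | culture experiments with nitrite oxidizers |
| ¹⁸ε_k,H2O,NOB | 15 | ‰ | culture experiments with nitrite oxidizers |
| ¹⁸ε_eq | 15 | ‰ | nitrite–water equilibrium at 4 °C (not temperature-modeled) |
| δ¹⁸O_H2O | 0 | ‰ V-SMOW | seawater |
| δ¹⁵N_OM | 11 | ‰ AIR | ambient organic matter; nitrified N tracks it within ±1‰ |
| δ¹⁸O_O2 (bottom water) | 27 | ‰ V-SMOW | deep-ocean value at ~170 µmol O₂ kg⁻¹ |
| ¹⁸ε respiration | 20 | ‰ | aerobic respiration, quoted range ±3‰ |

`X_AO` and the combined kinetic term `¹⁸ε_k,O2,AO + ¹⁸ε_k,H2O,AO` have no
consensus single values; the experimental literature supplies ranges. They
are therefore **required** configuration, with documented plausible ranges
X_AO ∈ [0.10, 0.25] and ε-sum ∈ [18.33, 32.56]‰. The ε-sum bounds were
back-solved so that, across both ranges, the produced-nitrite equation at
δ¹⁸O_O2 = 27‰ spans exactly −1‰ to +7‰ — the interval the endmember
bracket [−6, 0]‰ is quoted for. `NitrificationParams.typical()` uses the
range midpoints (0.175, 25.445‰). These midpoints are a convenience, not
an experimentally-determined pair.

Uncertainty propagation samples each named parameter **uniformly** over
its range (only ranges are available, not distributions), independently,
with a seeded generator, and reports 2.5/50/97.5 percentiles of δ¹⁸O_NTR.
At 10⁴ draws the median is stable to < 0.05‰.

## The synthetic column generator

A sequential-cell, steady-state forward model; per cell, working downward:

1. f_O2(z) = exp(−z/`o2_efold`) sets the local δ¹⁸O_O2 by Rayleigh
   fractionation with `eps_resp`;
2. a per-cell fraction `denit_frac` of the nitrate pool is denitrified
   (closed-system Rayleigh step, equal default ¹⁵ε and ¹⁸ε);
3. above `break_depth`, `ntr_add` µM of newly nitrified nitrate is mixed
   in with δ¹⁵N = δ¹⁵N_OM and δ¹⁸O = δ¹⁸O_NTR at the local δ¹⁸O_O2;
4. NH₄⁺, NO₂⁻, PO₄ and alkalinity follow simple stoichiometric
   bookkeeping (remineralized N : P = 16; 1 meq alkalinity per mmol N
   denitrified; 6% of denitrified N transits the nitrite pool; nitrification
   consumes the ammonium it oxidizes).

Gaussian measurement noise (s.d. 0.2‰ on both isotope columns, 2%
relative on concentrations, clamped at zero) is added in a separate,
seeded step; draws are consumed column-major (all δ¹⁵N, then all δ¹⁸O,
then concentrations) so adding columns never perturbs earlier draws.
Isotope values are reported only where nitrate exceeds 0.5 µM, mimicking
the analytical cutoff of the measured profiles.

**Default scenario.** An 11-cell grid (5-cm sampling above 20 cmbsf, 10-cm
below, to 85 cmbsf); bottom-water nitrate 36 µM at (4.4, 2.8)‰; O₂
e-folding depth 7.5 cm, so that dissolved O₂ is ~88% consumed by ~16 cmbsf
and essentially exhausted at the 50-cmbsf break — which is *why* the break
exists: nitrification is an aerobic process and shuts off with the O₂.
Per-cell denitrification fractions rise from 0.036 near the surface to
0.36 below the break; nitrified additions (0.3–6.1 µM per cell) peak near
45 cmbsf, mirroring the observed nitrifier-abundance maximum near the base
of the oxic interval. The denitrification fractionations default to
¹⁵ε = ¹⁸ε = 3‰: these are *expressed* (sediment-scale apparent) values —
transport limitation strongly mutes the organism-level 15–25‰ in sediment
pore waters — chosen so that drawing nitrate from 36 µM below 5 µM by
85 cmbsf produces isotope maxima near the observed ~18/~21‰ rather than
unphysically large ones.

With these defaults the noise-free column yields a two-segment δ¹⁸O–δ¹⁵N
fit with upper slope ≈ 1.9, lower slope ≈ 1.01, and a detected break one
grid cell above the true 50 cmbsf; with 0.2‰ noise the upper slope exceeds
1.5 and the break lands within one grid cell of 50 cmbsf in ≥ 95 of 100
seeded replicates (these numbers are computed by the test suite).

**What the generator does not emulate.** There is no diffusive or
advective transport: each cell's nitrate derives only from the cell above.
Real pore-water profiles are diffusion-smoothed, which (a) decouples
concentration drawdown from isotope enrichment and (b) lets the shallow
interval display a much steeper dual-isotope slope (≈ 3.2 in the field
data) at a much smaller δ¹⁵N rise than any transport-free closed-system
model can: in this generator the nitrified N (δ¹⁵N_OM = 11‰, far above
bottom-water nitrate at 4.4‰) necessarily drags the shallow pool δ¹⁵N
upward, capping the attainable shallow slope near 2. Passing tests
therefore demonstrate that the diagnostics recover a *qualitatively*
field-like two-regime structure (steep-above, unit-below), not that the
generator reproduces field slope magnitudes. The near-exhaustion O₂ tail
also implies residual-O₂ δ¹⁸O above 100‰ in the lowest oxic cells — a
standard Rayleigh consequence of f → 0, not a calibrated prediction.
Sulfate reduction and anammox are excluded (negligible/not detected in the
target setting).

## Diagnostics

- `ols_fit`: unweighted OLS of δ¹⁸O on δ¹⁵N (scipy), classical
  residual-variance slope standard error. The measured-profile analysis
  this mirrors did not state its fitting method; unweighted OLS in this
  orientation is the conventional choice, and errors-in-variables
  alternatives are deliberately out of scope but isolated behind this one
  operation.
- `segmented_fit`: candidate breaks default to midpoints of the observed
  isotope-bearing depths; each segment needs ≥ 3 points (`min_points`);
  the total-RSS minimizer wins; ties (beyond float jitter) go to the
  shallowest candidate. Rows with nitrate below the reporting threshold
  are excluded.
- `apparent_epsilon`: OLS slope of δ on −ln(c/c_ref); exact on linear-form
  Rayleigh data, < 3% low on exact-form data down to f = 0.1, invariant to
  joint rescaling of concentrations and reference.
- `classify_regime`: denitrification-only when |slope − 1| ≤ max(τ, 2·se),
  coupled when slope − 1 > max(τ, 2·se), indeterminate otherwise.
  τ defaults to 0.25, wide enough that the canonical field cases
  0.95 ± 0.10 and 3.2 ± 0.5 classify as intended. Quoted slope
  uncertainties are 1 s.e. throughout.

## Problem sizes

The test suite and acceptance script run desk-scale problems: 11-cell
columns, 100-replicate noise studies, 10⁴–2×10⁴ Monte-Carlo draws, chosen
as the smallest sizes at which the statistical checks (s.d. recovery,
percentile convergence, break-recovery rates) are stable.

## Known limitations

- No reaction-transport (diffusion/advection) modeling; see above.
- Nitrite is assumed non-accumulating wherever the endmember equation is
  applied; the simulated transient NO₂⁻ pool is bookkeeping only and does
  not feed back on isotopes.
- ¹⁸ε_eq is a 4 °C constant; no temperature dependence.
- O₂ never feeds back on rates; f_O2(z) is an imposed profile.
- Delta-space mixing and the rare-isotope Rayleigh convention introduce
  errors ≪ 0.1‰ over the simulated ranges, far below measurement noise.
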