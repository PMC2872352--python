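# Methods

This note documents the model formulation, the default parameter values
and why they were chosen, what the synthetic forcing does and does not
emulate, and the numerical choices. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scope and design

The package is a desk-scale box-model surrogate for a full 3D
hydrodynamic–contaminant simulation: the contribution is the *fate
process layer* (partitioning, interface fluxes, budgets), not the
hydrodynamics. Transport is therefore reduced to a small network of
well-mixed boxes with prescribed bidirectional exchange flows, and water
temperature/salinity are forcing inputs rather than prognostic fields.
The default geometry is three boxes (west/Marseillan, centre, east/Sète)
with total surface 7.5·10⁷ m², mean depth 4.06 m, two sea mouths (west
10 m³ s⁻¹, east 30 m³ s⁻¹) and inter-box exchanges of 50 m³ s⁻¹, giving
a flushing time of roughly three months. These flows are
order-of-magnitude choices, configurable in the YAML geometry block; no
claim of hydrodynamic realism is made.

## Congener properties

Five groups are modelled, labelled by chlorination degree; PeCDF and
HxCDF assemble two and four 2,3,7,8-substituted isomers respectively and
carry the arithmetic mean of member properties, because boundary
concentrations are reported as member sums. The shipped constants
(`data/congener_properties.tsv`) are **literature-range stand-ins**, not
measured values for this system:

| group | M (g/mol) | log Kow(25°C) | H (Pa m³/mol, 25°C) | ΔU_aw (kJ/mol) | ΔU_ow |
|-------|-----------|---------------|---------------------|----------------|-------|
| PeCDD | 354.5 | 7.40 | 1.00 | 55 | −25 |
| OCDD  | 460.8 | 8.20 | 0.68 | 60 | −25 |
| TCDF  | 306.0 | 6.10 | 1.44 | 50 | −20 |
| PeCDF | 340.4 | 6.50 | 0.50 | 52 | −22 |
| HxCDF | 374.9 | 7.00 | 0.74 | 55 | −23 |

Henry constants were fixed within their reported literature ranges such
that the rain-concentration closure (below) holds to ≤1.5% with the gas
washout term included. Degradation rates default to zero — PCDD/Fs are
treated as persistent — and budget reports show degradation lines as
zero unless configured otherwise. Every constant is overridable per
congener through a user TSV.

Temperature corrections use the van't Hoff form
`X(T) = X₂₅·exp(−(ΔU/R)(1/T − 1/298.15))` on [270, 320] K. With the
shipped ΔU_aw (≈50–60 kJ/mol ≫ RT) the dimensionless Henry constant
H′ = H/(RT) increases monotonically with temperature: volatility is
higher in summer.

Partition coefficients derive from Kow: `log₁₀ Koc[L/kg] = log Kow − 0.21`
(Karickhoff) and `Kdoc = 0.08·Kow`, both converted to m³ per kg organic
carbon; Kdoc < Koc always. These regressions are stand-ins for the
original model's unpublished parameterization and are the main
structural uncertainty in the partitioning.

## Deposition and scavenging closures

Two closures anchor the atmospheric pathway, and both are verified by
the acceptance script against the published tables:

* dry deposition `F = v_d·c_part_air` with default `v_d = 0.15 cm s⁻¹`,
  chosen because it reproduces the published annual dry-deposition row
  from the measured air particulate concentrations (OCDD to the printed
  precision);
* rain concentration `c_rain = c_gas/H′ + W_p·c_part_air` with default
  scavenging ratio `W_p = 2·10⁵`, which reproduces all five measured
  rain concentrations from the air particulate column within 1.5%.

Annualizations use a fixed 365-day year (3.1536·10⁷ s).

## Air–water exchange

Two-film model with the standard POP-modelling correlations, both
config-overridable:

* `k_w = 0.45·u₁₀^1.64 cm h⁻¹ · (Sc_w/600)^−0.5`, with the aqueous
  Schmidt number from a molar-mass-scaled diffusivity
  `D_w = 8.6·10⁻⁹/√M m² s⁻¹` and a freshwater viscosity correlation;
  `k_w(0) = 0` — no transfer at zero wind;
* `k_a = (0.2·u₁₀ + 0.3) cm s⁻¹ · (18/M)^0.305` (diffusivity-scaled from
  water vapour);
* `1/k_ol = 1/k_w + 1/(k_a·H′)` — resistances in series, so `k_ol` never
  exceeds either film velocity.

Only the freely dissolved phase exchanges; the net diffusive flux
vanishes at `C_diss = c_gas/H′`. Gross volatilization and absorption are
recorded separately so the budget table can report both lines. Whether
the original deposition velocity varied with wind is unknown; here it is
constant.

## Sediment exchange

The bed is a 5 cm surface mixed layer (porosity 0.8, solids
2600 kg m⁻³ → 520 kg dry weight per m³ bulk) over a fixed deep boundary.
Boundary sediment concentrations printed in ng m⁻³ are interpreted as
per m³ *bulk* sediment and converted to ng per kg dry solids by dividing
by 520; this unit reading is a documented choice and configurable.

Default process rates, derived once from the published annual budget and
standard magnitudes rather than fitted at run time:

* settling `w_s = 1 m day⁻¹` (fine-particle range);
* resuspension `r_s = 3.6·10⁻⁹ kg m⁻² s⁻¹` (≈0.114 kg m⁻² yr⁻¹) — the
  value implied by the published resuspension row divided by the
  sediment boundary concentrations, which lands four of the five
  congeners' resuspension fluxes at the printed values;
* sediment–water exchange velocity `k_sw = 10⁻⁶ m s⁻¹` (≈9 cm day⁻¹,
  the standard benthic-boundary-layer magnitude);
* surface↔deep exchange velocity γ = 2·10⁻¹⁰ m s⁻¹ (bioturbation-scale
  diffusivity over the layer thickness), burial 1 mm yr⁻¹.

Porewater concentration assumes local equilibrium with the solids'
organic carbon (`f_oc = 0.03`): `c_pore = c_surf/(Koc·f_oc)`.
Resuspension is constant in time — no shear-stress or wind dependence —
with a config hook for replacing it.

## Ecology

A generic 2-phytoplankton / 2-zooplankton / bacteria / detritus / DOC /
nutrient model supplies the organic-carbon pools; the original coupled
ecosystem model's equations are not published with the main text, so
these are the package's own standard closures: Monod nutrient and
saturating light limitation, Q10 = 2 temperature dependence, Holling-II
grazing (assimilation 0.7, of which 0.3 respired), linear mortality to
detritus, first-order detritus dissolution to DOC, bacterial DOC uptake
(growth efficiency 0.3). Carbon accounting is closed: the sum of the
carbon-pool tendencies equals gross primary production minus total
respiration, and a pool at zero never receives a negative tendency (the
integrator needs no clipping in the tested regime). The nutrient is
consumed and regenerated with a Redfield C:N quota.

Defaults were tuned only to yield a plausible Mediterranean-lagoon
seasonal cycle — a late-winter/spring phytoplankton transient, POC of
order 10²–10³ mg C m⁻³, DOC of order 10²–10³ mg C m⁻³ — and make no
claim of matching the original ecosystem model. POC = plankton +
bacteria + detritus carbon; mg C m⁻³ converts to the partitioning
module's kg C m⁻³ with a fixed 10⁻⁶ factor. Contaminants exert no
toxicity feedback on the plankton.

## Boundary forcing and the synthetic year

The packaged boundary table carries the measured compartment
concentrations (gas, air particulate, rain, sediment, river, open sea)
for the five groups; it is the default forcing and is held constant in
time — a strong simplification, as real air concentrations vary by
orders of magnitude between events.

The synthetic generator emulates one Thau-like year on a regular grid:
seasonal air/water temperature sinusoids spanning ≈5–29 °C (February
minimum, August maximum; small AR(1) noise on air temperature), salinity
27–40, Weibull wind (shape 2, mean ≈5.5 m s⁻¹ in 3-h blocks), Poisson
rain events (~40 yr⁻¹) with gamma depths renormalized so the annual
total is met exactly, and rain-driven river runoff from a 280 km²
catchment (runoff coefficient 0.2, 2-day recession, 0.05 m³ s⁻¹
baseflow). The default annual rain total is **102 mm**: the published
annual wet-deposition fluxes divided by the rain concentrations imply
≈0.102 m of scavenging rain in the simulated year, and matching that
makes the generated year's wet-deposition column line up with the
published one. Identical seeds give bit-identical series.

What the synthetic year does *not* emulate: the actual 2005 storm
calendar, diel cycles, wind-direction effects, spatially varying
meteorology, and event-correlated air concentrations. Passing tests on
this forcing therefore demonstrate internal consistency and the stated
process closures — not skill against field measurements, which would
require the unpublished station data.

A known tension: the measured river concentration of OCDD
(1842 ng m⁻³) combined with any realistic annual freshwater inflow makes
the river the largest OCDD input in this configuration, whereas the
original study found riverine loads minor for all congeners. The river
term here is a plain bidirectional exchange with the measured
concentration; users studying source apportionment should treat the
river column (and the runoff coefficient) as the most uncertain inputs.

## Numerics

Explicit Euler with a default 600 s step, chosen for transparent mass
accounting. Before each step the fastest first-order loss rate is
evaluated and the step is subdivided so that `rate·dt ≤ 0.5`; a negative
concentration anywhere aborts the run with a diagnostic rather than
clipping. The sediment layer update enforces its own stability bound.
The per-step operator order is ecology → partitioning → interface fluxes
→ transport → degradation, with forcing frozen within a step.

Flux records accumulate into daily bins (half-open intervals [t, t+Δ)),
which makes monthly aggregation exact: monthly loads sum to the annual
integral with no double counting. The mass ledger tracks, per congener,
the combined water + surface-sediment inventory against the accumulated
boundary fluxes (air–water, river, sea, burial, deep-layer exchange,
degradation); internal settling/resuspension/diffusion cancel by
construction. Runs in this configuration close the ledger to ≈10⁻¹⁴
relative; the test suite enforces ≤10⁻⁶ on a full synthetic year and
≤10⁻⁹ on closed systems. Steady states are insensitive to the Euler
step (the fixed point of the scheme is the exact balance), which is how
the analytic `C* = inputs/losses` check is performed; pure-mixing
transients are verified against the closed-form exponential by
integrating the transport tendencies with a high-order adaptive solver.

Problem sizes used by the shipped tests: one 365-day three-box year at
dt = 600 s for the budget and conservation checks, a 150-day single-box
run for the steady-state check, and a 70-day two-box closed system
(>10⁴ steps) for conservation — all chosen as the smallest runs that
exercise the full seasonal cycle or the stated step counts.

## Known limitations

* No hydrodynamics: box exchange flows are prescribed, so spatial
  gradients are only as good as the three-box resolution.
* Constant boundary concentrations in air, river, sea and deep sediment.
* Equilibrium (instantaneous) sorption; no kinetics, no black carbon,
  no mineral-solids sorbent term by default (a config factor can add
  one), no Freundlich nonlinearity.
* Congener grouping by mean properties ignores within-group property
  spread.
* The ecology is a generic stand-in; its parameters are not calibrated
  to any dataset.
* No toxicity, bioaccumulation, TEQ weighting, or sediment diagenesis
  beyond the two-layer exchange.
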