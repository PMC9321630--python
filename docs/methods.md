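# Methods

This note documents the model equations as implemented, the parameter
defaults and their rationale, the numerical choices, what the synthetic
forcing does and does not emulate, and known limitations.

## Plant hydraulics

Soil-to-canopy conductance declines with water potential following a
cumulative Weibull, k(Ψ) = k_max·exp(−(|Ψ|/b)^c), with per-species (b, c)
taken from the packaged registry and a shared k_max = 1.5 mmol m⁻² leaf s⁻¹
MPa⁻¹ (species-level measurements of k_max are unavailable; the shared value
is consistent with estimates for temperate species spanning similar rainfall,
and its influence is quantified by the `kmax_half` sensitivity run). Percent
loss of conductivity is PLC = 100(1 − k/k_max); the potential at fractional
loss x is Ψx = −b(−ln(1−x))^(1/c). `fit_bc_from_pxx` inverts (P12, P50) to
(b, c) in closed form; it deliberately ignores P88 because the tabulated P88
values are not mutually consistent with (b, c) for several species — (b, c)
are authoritative, printed thresholds are validated metadata.

Hydraulic failure is k_crit = 5 % of k_max. Cavitation has no memory:
conductance is a pure function of the current potential, i.e. full recovery
on rewetting. This overstates recovery for species with poor refilling
capacity and makes multi-year PLC trajectories optimistic.

## Stomatal optimisation

The optimiser maximises Profit = CG − HC over n = 1000 uniformly spaced Ci
candidates in [Γ*, Cs] (spacing ≈ 0.36 μmol mol⁻¹ at ambient CO₂), rather
than co-optimising (Ci, g) per candidate Ψleaf; this is the computational
shortcut that makes the scheme cheap, and the test-suite verifies it matches
a dense Ψ-space co-optimisation to within one grid step. Per candidate:
A(Ci) from Farquhar; g_sc = A/(Cs−Ci); g_sw = 1.57 g_sc (diffusivity ratio,
boundary layer assumed non-limiting); E_leaf = g_sw·VPD/P_atm; Ψleaf as the
least-negative root of the supply relation E = k(Ψ)(Ψsoil,w − Ψ) — the
ascending, physiologically stable branch. CG normalises A by the maximum
over feasible candidates; negative-A candidates get CG = 0 and can never
win. Two feasibility gates are implemented and individually switchable
(both on by default): E ≤ E_crit (the supply maximum over allowed
potentials) and k(Ψleaf) ≥ k_crit. If the soil is beyond critical, no
candidate is feasible, or no profit is positive, the closed solution is
returned (g = 0, E = 0, Ψleaf = Ψsoil,w, A = −Rd).

Numerics: the root solve is a vectorised bisection over all candidates
simultaneously (45 iterations, interval ≪ 10⁻⁹ MPa, supply residual well
under 10⁻⁶ mmol m⁻² s⁻¹); the supply-curve maximum is found by Brent root
finding on the stationarity condition. Exact profit ties (typically among
zero-profit candidates) break toward the less negative Ψleaf — the
hydraulically safer operating point — making output deterministic.

The scheme is known to keep stomata marginally open at very negative Ψleaf
(small CG can still beat HC near saturation of the cost term). This is a
property of the optimisation target, surfaced in diagnostics, not patched.

## Photosynthesis

Standard minimal C3 model: A = min(Ac, Aj) − Rd with Ac Rubisco-limited and
Aj RuBP-regeneration-limited; J from a non-rectangular hyperbola of absorbed
PAR (curvature 0.7, quantum yield 0.26 mol e⁻ mol⁻¹); TPU limitation
omitted. Temperature responses are Bernacchi-type Arrhenius for Kc
(404.9 μmol mol⁻¹, Ha 79.43 kJ mol⁻¹), Ko (278.4 mmol mol⁻¹, 36.38), Γ*
(42.75 μmol mol⁻¹, 37.83) and Rd (46.39), and peaked Arrhenius for Vcmax
(Ha 65.33, Hd 200 kJ mol⁻¹, ΔS 640 J mol⁻¹ K⁻¹) and Jmax (43.54, 200, 640).
Jmax25 = 1.67 Vcmax25 and Rd25 = 0.015 Vcmax25 are declared defaults (the
host land-surface scheme's exact ratios for these runs are not published);
all constants are frozen in `constants.py` for reproducibility. Vcmax25 is
species-specific where measured, else the cross-species eucalypt average
86.88 μmol m⁻² s⁻¹.

Leaf temperature defaults to isothermal (T_leaf = T_air); an iterative
energy-balance mode (two-sided sensible exchange against a configurable
boundary-layer heat conductance, ≤ 5 iterations, 0.01 °C tolerance) is
provided so the sensitivity is testable, but the full canopy energy balance
of a land-surface host is out of scope.

## Soil water

Six layers (0.1, 0.25, 0.65, 1.0, 1.3, 1.3 m; 4.6 m total), vertically
uniform texture by default with per-layer override. Campbell retention
Ψs = ψe(θ/θsat)^(−b) and conductivity K = Ksat(θ/θsat)^(2b+3); defaults
θsat 0.45, ψe −0.0015 MPa, b 5, Ksat 20 mm h⁻¹ (a loam). Root fractions
decay exponentially with depth (e-folding 0.5 m). The root-zone potential
seen by the plant is the K·root-fraction-weighted mean of layer potentials,
which shifts uptake toward deeper, wetter layers as the surface dries; a
fully dry profile falls back to the deepest layer with a warning.

Vertical movement is a tipping-bucket cascade in place of a Richards solver:
infiltration fills layers top-down with saturation excess as runoff;
drainage releases water above field capacity (θ at −0.033 MPa) at a rate
capped by K(θ); the bottom layer drains freely. The scheme is exactly
conservative (residual < 10⁻⁹ mm over 10³ randomised steps by test). Soil
evaporation is omitted — water leaves only via transpiration, runoff and
drainage — which biases the store wet in open canopies; the hydraulics only
couple through Ψsoil,w, so the optimiser logic is unaffected.

## Simulator

Big-leaf canopy: mean absorbed PAR per unit leaf area from Beer's law
(extinction 0.5, PAR = 2.3 μmol J⁻¹ of shortwave); leaf transpiration scaled
by LAI to canopy flux (mm, via 18.015 g mol⁻¹). LAI is prescribed (constant
or 12-month climatology), never prognostic. VPD is derived from air
temperature (Magnus) and generated vapour pressure, floored at 0.05 kPa —
without a floor the optimum degenerates to unboundedly open stomata as
VPD → 0. Spin-up repeats the first forcing year until total storage changes
by < 0.1 mm between cycles, at most 5 cycles (prescribed LAI makes the store
stabilise within a few annual cycles). Monthly Ψleaf means use calendar
months over all steps by default, with a switch to non-closed
(approximately daylight) steps only, since the sub-daily-to-monthly
aggregation convention is ambiguous. Gaps or NaNs in forcing are errors, not
interpolated.

Scenarios apply uniform multiplicative perturbations (precipitation ×0.8;
CO₂ ×2 ≈ 800 μmol mol⁻¹) to otherwise identical forcing; the sensitivity
suite perturbs k_crit (×2), k_max (×0.5), LAI (×1.4) and LAI+CO₂. Runs are
bit-deterministic given forcing and config (hash and seed recorded in the
output).

## Synthetic forcing and SPI

The generator emulates 3-hourly single-site meteorology: shortwave from
solar geometry (clear-sky transmissivity 0.72, 0.35 on rain days); air
temperature = annual mean + seasonal cosine (Southern-Hemisphere phase) +
diurnal cosine (peak 14:00) + AR(1) daily anomalies (ρ 0.7, σ 2 °C);
vapour pressure from daily relative humidity clipped to [0.2, 1.0] (so VPD
is derived, never inconsistent with temperature); rainfall as daily
Bernoulli occurrence (default frequency 0.18) with gamma depths (shape 0.8)
scaled to the target mean annual precipitation (default 700 mm yr⁻¹,
mid-range of the species' 344–1424 mm yr⁻¹ gradient), spread evenly over
the day's steps. A drought block multiplies occurrence frequency by a
configurable factor over a date span, creating control-versus-drought
pairs. The generator does not emulate: spatial rainfall structure, weather
fronts or multi-day wet spells, humidity–rainfall co-variability beyond the
rain-day RH shift, longwave radiation, or trends. Passing tests therefore
demonstrate correct model mechanics under plausible forcing statistics, not
skill against observed meteorology.

The acceptance fixtures use three years with the last two as a drought
block (rain frequency halved): a severe multi-year drought in which the
directional scenario contrasts (drier → deeper Ψmin; doubled CO₂ → relief;
halved k_max → less PLC; +40 % LAI → more, offset by CO₂) are expressed at
a single site. At such a site the control itself approaches hydraulic
failure — the regime the landscape-scale hotspots correspond to.

SPI follows McKee: rolling window sums (default 6 months), gamma fitted by
MLE over the baseline (Thom approximation fallback), zero totals absorbed
in a mixed CDF H(x) = q + (1−q)G(x), then Φ⁻¹(H). The construction is
scale-invariant and standardised over its baseline by design; both are
tested.

## Limitations

No cuticular conductance (g_min), mesophyll conductance, non-stomatal
drought downregulation of Vcmax, xylem–leaf potential separation,
capacitance, groundwater, soil heat or freezing. PLC/Ψ thresholds are
indicators of hydraulic stress consistent with mortality risk, not a
mortality model. Landscape-scale gridded application, satellite
validation and species-distribution modelling are out of scope; the
`range_summary` diagnostics operate on whatever set of (site, species)
runs the user supplies.
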