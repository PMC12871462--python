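# Methods

## The microcosm model

The synthetic-data generator emulates stable-isotope-probing
incubations of methane-oxidizing sediment in sealed bottles: 20 g of
air-dried sediment (20% moisture) under a 0.105-L headspace (125-ml
bottle minus sediment) at 20 °C and 1 atm, CH₄ targets of 2, 10, 50,
100, 250 and 500 ppmv crossed with a 99 atom% ¹³CH₄ label and an
unlabeled control, in triplicate, for 30 days. CH₄ is re-injected to
the target every 3 days; on day 15 the entire headspace is exchanged
for synthetic air (CO₂-free) before injection continues. An autoclaved
(sterile) control at 2 ppm has oxidation and respiration disabled, and
an ambient-air control at 1.9 ppm has its headspace fully exchanged
every cycle to hold near-atmospheric CH₄ and provide natural-abundance
baselines.

State is a set of ¹²C/¹³C mol pools: headspace CH₄ and CO₂, sediment
organic carbon (TOC), and per-compound PLFA pools (a slice of TOC).
Between events the CH₄ pool is integrated with a fixed-step
explicit update (classic fourth-order Runge–Kutta on the total, step
≤ 0.5 h); consumption follows Michaelis–Menten kinetics on the aqueous
CH₄ concentration, assuming instantaneous headspace–water equilibrium
through the Bunsen coefficient. The dissolved CH₄ *inventory* itself
(≈0.1% of the headspace inventory at 20% moisture) is neglected: the
aqueous phase sets the rate, not a reservoir. The oxidized carbon
stream carries the CH₄ pool's isotope composition modified by a kinetic
fractionation ε_ox (ratio of rate constants α = 1 + ε_ox/1000); a
fraction `f_assim` of oxidized carbon enters TOC (and `plfa_yield` of
that enters PLFA pools by a fixed allocation), the remainder enters
headspace CO₂ together with an unlabeled background respiration flux.
Replenishment adds exactly the deficit to the target; swaps zero the
headspace and log the vented ¹³C. Mass and isotope conservation
therefore hold to machine precision by construction, which is what
makes the closure tests meaningful.

Measurement noise is applied to observations only, never to state, so
the generative truth remains recoverable. Concentration-like
observables (CH₄ and CO₂ ppm, TOC %, PLFA concentrations) receive
multiplicative lognormal noise with coefficient of variation
`measurement_cv` (default 0.05, typical of GC quantification). Isotope
observables (δ¹³C-CO₂, δ¹³C-TOC, FAME δ¹³C, the CH₄ ¹³C atom fraction)
receive noise on the ¹³C/¹²C ratio scale with standard deviation
`delta_sd`/1000 (default 0.2‰, typical IRMS precision). A single CV on
δ values would be ill-defined across zero and hundreds of times coarser
than real isotope-ratio measurements, which would make labeled/control
differencing at low doses meaningless; the two-channel noise model
reflects how these instruments actually behave. Seeding uses one master
seed with per-bottle substreams derived from a stable hash of
(treatment, replicate), so identical configurations give byte-identical
datasets.

### Generative defaults

| parameter | default | rationale |
|---|---|---|
| `vmax_true` | 115.9 ng CH₄ g⁻¹ h⁻¹ | gives an initial rate of 90.7 ng g⁻¹ h⁻¹ at 500 ppm with the default Km |
| `km_aq_true` | 196.2 nM | 138.8 ppm headspace at 20 °C, β = 0.034 |
| `f_assim` | 0.60 | mid-range of the 0.53–0.73 efficiencies typical of high-affinity methanotrophs |
| `epsilon_ox` | −20‰ | typical kinetic fractionation of microbial CH₄ oxidation; immaterial at 99 atom% label |
| `toc0`, `delta_toc0` | 0.6%, −24.5‰ | oligotrophic cave sediment organic carbon |
| `respiration_rate`, `delta_resp` | 10 ng C g⁻¹ h⁻¹, −25‰ | synthetic-only background CO₂ source giving realistic control δ¹³C-CO₂ baselines |
| `plfa_yield`, allocation | 0.06; 16:0 0.45, 16:1ω7c 0.35, other 0.20 | dominant methanotroph fatty acids receive most label |
| `plfa_background`, `delta_plfa0` | 2500/1800/3200 ng g⁻¹, −28‰ | viable-biomass background in sediment |
| `delta_ch4_unlabeled` | −40‰ | tank CH₄ |
| `delta_methanol` | −38.7‰ | derivatization reagent; carried into endpoints because the FAME correction needs it |

Background respiration, the unlabeled-tank δ¹³C, the methanol δ¹³C and
the PLFA background pools are synthetic-only plumbing: they give the
control treatments realistic natural-abundance baselines but are not
part of the analysis chain's claims. What passing tests on this
generator shows is that the *analysis* is correct and unbiased when its
assumptions hold; it does not show robustness to features the generator
omits — microbial growth and lag, temperature drift, diffusion-limited
gas exchange, pressure excursions after repeated injections (the
simulator holds 1 atm throughout), or community shifts.

## Rate estimation

Initial oxidation rates are estimated per bottle from the early
drawdown of a replenishment cycle. The default (`first_order`) fits
ln(ppm) against time and reports k·C₀ at the window start, converted to
ng g⁻¹ h⁻¹ through the ideal-gas headspace CH₄ mass (molar mass 16.04
for both isotopologues) and the dry sediment mass; `linear` uses the
−slope of ppm vs. time. Standard errors propagate from the regression
slope. Because the reaction is zero-order above Km and first-order
below it, a ln-fit spanning a large drawdown overstates the initial
rate at high concentrations: the default window therefore takes
observations from the cycle start until CH₄ falls below
(1 − `max_drawdown`) of its starting value (minimum three points).
The pipeline uses `max_drawdown = 0.30` as its default — under 5%
measurement noise a tighter window makes the slope estimate unstable —
and simulates a dedicated short assay with 0.25-h sampling for this
purpose, mirroring the practice of measuring potential rates in
separate bottles rather than in the 30-day microcosms. On noiseless
data, windows of 1–2% drawdown with 0.02-h sampling recover the
generative (Vmax, Km) to better than 1% through the full
simulate–measure–fit chain.

## Kinetics fitting

v = Vmax·S/(Km+S) is fitted by unweighted nonlinear least squares
(no weighting scheme is assumed for the rate data) with eight Km
starting values log-spaced from a tenth of the smallest to ten times
the largest concentration; the best local optimum by sum of squared
errors is kept and must beat a 200×200 grid search in the tests.
Standard errors come from the Jacobian-based covariance at the optimum.
Degenerate inputs (all-zero rates, universal optimizer failure) yield
`converged=False` rather than an exception. Km is fitted in ppm — the
measured axis — and converted to aqueous nM afterwards with the molar
volume evaluated at the incubation temperature (24.055 L mol⁻¹ at
20 °C), the convention under which 138.8 ppm maps to 196 nM; using the
standard-temperature molar volume instead would give ≈210 nM.

## ¹³C budget

All gas-phase ¹³C inventories count atoms (ideal-gas mol × atom
fraction) and convert to mass with the isotopic molar mass
13.003 g mol⁻¹. The printed-form sediment excess, 10·TOC%·ΔAT%·10 in
mg kg⁻¹, folds its unit conversions into a round factor of 100 and so
reports mass on the average-carbon (≈12 g mol⁻¹) scale; it is kept
exactly in that form as `excess_13c_soc`, while the per-bottle budget
converts the TOC atom-fraction excess through mol C × 13.003 so that
the sediment, CO₂ and residual-CH₄ terms are commensurable and the
ledger closes.

Efficiency is normalized by the *excess* ¹³C supplied — injected CH₄-C
× (label atom fraction − natural atom fraction) — because the
numerator is itself an excess over the unlabeled control; normalizing
by gross label ¹³C would bias every efficiency low by ≈1% relative
(the natural-abundance share of the label). The gross supplied mass is
reported alongside. Supplied label counts every injection including
those consumed before the day-15 swap, consistent with the
complete-consumption regime (each cycle's CH₄ is exhausted well before
the next injection, so each injection adds the full target amount).
Baseline subtraction for CO₂ and TOC uses the paired unlabeled (or
ambient) control mean rather than a constant. Negative excess values —
possible within noise at the lowest dose — are flagged (`qc_negative_excess`),
never clamped, so the error structure survives into downstream
statistics.

## PLFA

The methylation correction interprets n as the number of carbon atoms
in the *free* fatty acid (the methyl ester has n+1); this is the only
reading under which the mass balance
δ_PLFA = [(n+1)·δ_FAME − δ_methanol]/n is exact, and it makes the
correction linear in δ_FAME with slope (n+1)/n. The methanol δ¹³C is a
required input with no default — it is a property of the reagent batch.
Dose–response regressions (concentration and corrected δ¹³C against
total CH₄ added) are ordinary least squares on treatment means, as
dose–response figures conventionally plot means; compounds with
nonpositive slopes are flagged.

## Upscaling

The regional sink is a product of point or distributional parameters;
the point estimate always uses central values (mean, exp(μ) for
lognormal, midpoint for uniform) and the 95% interval comes from seeded
Monte-Carlo draws (2.5/97.5 percentiles). The shipped example scenario
(5×10⁵ km² karst area, 100 kg reactive sediment m⁻², 1.28 ng g⁻¹ h⁻¹,
fully active year) is illustrative — regional estimates are only as
good as their survey inputs, which must be user-supplied. Habitat
summaries bin records into half-open (low, high] CH₄ intervals
(matching "≤5 ppm" and ">5 but ≤60 ppm" conventions) and compare
habitats all-pairs with Mann–Whitney U tests under Benjamini–Hochberg
adjustment at 0.05; rank-based tests suit the heavy-tailed,
non-normal rate compilations these summaries are built from. Group
letters come from the insert-and-absorb compact-letter-display
algorithm, implemented here because no installed package provides it.

## Numerical choices and edge cases

- δ¹³C below −1000‰ and atom percents at or outside [0, 100] raise
  domain errors; δ = −1000‰ maps to exactly zero ¹³C.
- δ¹³C-CO₂ is NaN while the CO₂ pool is empty (post-swap synthetic
  air); inventory code treats an empty pool as zero ¹³C.
- Observation rows at event times report the post-event state with the
  event flagged; the pre-event state is the previous sample.
- The ln-fit falls back to linear regression (with a warning) if the
  window contains nonpositive concentrations.
- Table schemas embed units in column names and are enforced on both
  write and read; violations report file, row and column.

## Problem sizes

Default test and pipeline runs use the full 42-bottle design at 12-h
sampling (30 days), fine-sampled rate assays of 6–24 h, 200-replicate
noise studies for the kinetics fit and 100–200-replicate permutation
and level checks; these sizes keep the whole suite under a minute on a
laptop while leaving Monte-Carlo standard errors well inside the
asserted tolerances.
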