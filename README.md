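# karstmethane

Quantitative analysis of atmospheric methane oxidation by cave-sediment
methanotrophs: seeded simulation of ¹³CH₄/¹²CH₄ microcosm incubations,
oxidation-rate and Michaelis–Menten kinetics estimation, a ¹³C mass
balance that yields carbon assimilation efficiency, PLFA δ¹³C
derivatization correction, and scenario-based upscaling of rates to a
regional methane sink.

Karst caves hold trace CH₄ (often below ambient air) and host
high-affinity atmospheric methanotrophs (USCγ-type, family *Ca.*
Methyloligotrophaceae). Quantifying how fast these communities oxidize
CH₄, how much of the oxidized carbon they assimilate into biomass, and
what that implies at regional scale requires a chain of standard but
error-prone calculations — headspace/aqueous unit conversions, isotope
mass balances, nonlinear kinetics fits. This package implements that
chain as tested, reusable code for microbial ecophysiologists and
biogeochemists, together with a synthetic-data generator so every stage
is testable without any measurement campaign.

## The models

**Oxidation kinetics.** CH₄ consumption follows Michaelis–Menten
kinetics on the *aqueous* concentration,

    v = Vmax · S / (Km + S),

with the headspace mixing ratio x (ppmv) mapped to dissolved
concentration through the Bunsen solubility coefficient β,

    C_aq = β · x·P / V_m(T),

where V_m is the ideal-gas molar volume at the incubation temperature
(24.055 L mol⁻¹ at 20 °C; β = 0.034 for CH₄ at 20 °C, so 138.8 ppm ↦
196 nM). Initial rates come from ln-linear (first-order) or linear
regression over the early drawdown of a replenishment cycle; Km is
fitted on the measured ppm axis by multi-start nonlinear least squares
and converted to nM afterwards. The per-cell specific affinity is
a⁰ₛ = Vmax/Km with cell density from marker-gene copies (one gene per
cell by default).

**¹³C mass balance.** δ¹³C values convert to ¹³C atom percent via
AT% = 100·(δ/1000+1)·Rst / (1+(δ/1000+1)·Rst) with Rst the ¹³C/¹²C
ratio of VPDB. Sediment excess ¹³C is 10·TOC%·(AT%ₗₐᵦ−AT%ᵤₙₗₐᵦ)·10
(mg kg⁻¹); CO₂ inventories use ideal-gas mol counts and δ¹³C-CO₂.
Assimilation efficiency is the sediment-organic-carbon excess ¹³C as a
share of the excess ¹³C supplied as labeled CH₄; recovery sums residual
CH₄, CO₂ and sediment pools. PLFA δ¹³C values are corrected for the
methyl carbon added during transesterification:
δ_PLFA = [(n+1)·δ_FAME − δ_methanol]/n.

**Upscaling.** sink (Tg yr⁻¹) = area × areal reactive-sediment mass ×
rate × active fraction × hours, with seeded Monte-Carlo intervals when
parameters are distributions, plus emission-offset percentages and
habitat-stratified rate summaries (rank-based all-pairs comparison with
Benjamini–Hochberg letters).

## Worked example

Run the full pipeline (simulate a 30-day triplicate microcosm set at
2–500 ppm plus a fine-sampled initial-rate assay, then analyze it):

```bash
karstmethane run --seed 1 --out-dir demo --mode full
cat demo/summary.txt
```

```
config_sha = 9d8dc35146a7  seed = 1
kinetics: Vmax = 139.9 ng/g/h, Km = 159.8 ppm (226 nM), R^2 = 1.000
13C-100ppm: efficiency = 58.7%, recovery = 99.5%
13C-10ppm: efficiency = 57.0%, recovery = 95.9%
13C-250ppm: efficiency = 61.1%, recovery = 100.5%
13C-2ppm: efficiency = 63.5%, recovery = 107.2%
13C-500ppm: efficiency = 58.5%, recovery = 97.5%
13C-50ppm: efficiency = 60.2%, recovery = 100.3%
```

The generative truth behind this dataset has Vmax = 115.9 ng g⁻¹ h⁻¹,
Km = 196 nM (138.8 ppm) and an assimilated fraction of 0.60: under 5%
measurement noise the fitted Km lands at 226 nM and the six per-treatment
efficiencies scatter between 57 and 64% around the true 60%, with ¹³C
recoveries near 100% — the scale of scatter one should expect from real
triplicate incubations. `demo/` also holds the tidy datasets
(`headspace.csv`, `endpoints.csv`, `plfa.csv`), per-bottle `rates.csv`,
`kinetics.json`, the per-treatment `budget.csv` and `plfa_corrected.csv`.

Library use mirrors the CLI:

```python
from karstmethane import headspace_to_aqueous, specific_affinity

km_aq = headspace_to_aqueous(138.8, temperature=20, pressure=1, bunsen=0.034)
# 196.2 nM
a0s = specific_affinity(vmax=90.7, km_aq=km_aq, gene_copies_per_g=1e7)
# liters cleared per cell per hour
```

## Layout

- `src/karstmethane/simulate.py` — synthetic microcosm generator
- `src/karstmethane/kinetics.py` — rates, Michaelis–Menten, conversions
- `src/karstmethane/isotopes.py` — atom-percent algebra, ¹³C budget
- `src/karstmethane/plfa.py` — FAME correction, dose–response
- `src/karstmethane/upscaling.py` — regional sink, habitat summaries
- `src/karstmethane/io.py`, `pipeline.py`, `cli.py` — validated CSV I/O,
  pipeline runner, `karstmethane` console script
- `docs/methods.md` — model assumptions, parameter choices, limitations
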