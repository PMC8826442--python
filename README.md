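# spongeground

Quantitative analysis chain for dense Arctic seamount sponge grounds:
image-survey density and biomass estimation, an allometric community carbon
budget, a Bayesian two-isotope diet mixing model, and radiocarbon age and
growth inference — together with a seeded synthetic-community generator so
the whole chain is testable without cruise data.

The package is written for benthic ecologists and isotope biogeochemists who
want to reproduce, probe, or re-parameterize the carbon bookkeeping of a
high-Arctic *Geodia* sponge ground: a community sitting under permanent sea
ice, with export fluxes (< 1 g C m⁻² yr⁻¹) that cover less than 1% of its
metabolic carbon demand, apparently subsidized by refractory detritus of an
extinct seep fauna (siboglinid worm tubes) trapped in the underlying
spicule-tube mat.

## The models

**Allometric carbon budget.** Individual wet weight follows the cubic size
law WW (kg) = 0.0003·L³ (L in cm); dry weight is a fixed fraction of wet
weight (default 0.187) and organic carbon 30% of dry weight. Pumping and
respiration are volume-specific power laws per litre of sponge,

    L_pumped = 0.4952 · V^(−0.52),     O₂ = 25.5 · V^(−0.23),

multiplied by V for per-individual totals (net exponents 0.48 and 0.77).
Because the absolute units of these literature rate laws are not recoverable
from the coefficients, both carry calibration multipliers that reconcile
community totals with independently known rates (25 mmol O₂ m⁻² d⁻¹ over the
summits; 1640 L m⁻² d⁻¹ in the densest category); the calibration is logged
in every report. Oxygen demand converts to carbon as
flux × 365 × RQ × 12.011/1000.

**Diet mixing model.** For consumer i and isotope j ∈ {δ¹³C, δ¹⁵N},

    x_ij ~ Normal( Σ_k p_k (μ_jk + λ_j),  Σ_k p_k²(ω_jk² + τ_j²) + σ_j² ),

with source means/SDs (μ, ω), trophic enrichment factors (λ, τ),
p ~ Dirichlet(α) on the simplex and half-Cauchy residual scales σ_j —
sampled by Metropolis-within-Gibbs on softmax-transformed proportions.
Isotopic niches are summarized by standard ellipse areas
(SEAc = π√(λ₁λ₂)·(n−1)/(n−2), requiring n ≥ 3).

**Radiocarbon.** Conventional ages use the Libby mean life:
age = −8033·ln(1 + Δ¹⁴C/1000). Radial growth rates come from the OLS fit of
section age on radial distance (rate = 1/slope), and the adult sponge age is
the juvenile settlement baseline plus the radial age span.

## Worked example

```python
>>> import spongeground as sg
>>> sg.annual_carbon_demand(25.0, rq=1.0)      # g C m-2 yr-1
109.600375
>>> sg.annual_carbon_demand(25.0, rq=0.77)
84.39228874999999
>>> sg.water_column_height(1640.0)             # m of column per year
598.6
>>> sg.d14c_to_age(-527.0)                     # conventional 14C yr
6013.98490030781
>>> b = sg.individual_biomass(17.0)            # a median-size sponge
>>> round(b.ww_kg, 3), round(b.c_kg * 1000, 1)
(1.474, 82.7)
```

A 25 mmol O₂ m⁻² d⁻¹ community flux corresponds to a demand of ~110 g C m⁻²
yr⁻¹ at a respiratory quotient of 1 (85 at RQ 0.77); a community filtering
1640 L m⁻² d⁻¹ processes a ~600 m water column in a year; sediment with
Δ¹⁴C = −527‰ dates to ~6000 conventional years; and a single median (17 cm)
sponge on 1 m² already stocks ~83 g of organic carbon.

The full synthetic study runs in one call (or `spongeground run --outdir ...`
from the shell):

```python
>>> from spongeground.pipeline import run_pipeline
>>> report = run_pipeline()
>>> round(report["budget"]["carbon_demand_gC_m2_yr"], 1)
109.6
>>> round(100 * report["mixing"]["microbial"]["mean_proportions"]["siboglinid tubes"])
40
```

i.e. the calibrated synthetic community demands ~110 g C m⁻² yr⁻¹ over the
dense summit categories, and the mixing model attributes roughly 40% of the
adult *G. parva* diet to siboglinid-tube detritus under the
microbially-mediated enrichment scenario (0.5 ± 0.5‰ for ¹³C, 1.5 ± 0.5‰
for ¹⁵N).

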