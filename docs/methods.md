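# Methods

This note documents the models, parameter choices, numerical conventions,
and limitations of the `spongeground` analysis chain. Nothing here reports a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic community generator

The generator (`spongeground.synth`, parameterized in
`spongeground.defaults`) emulates an image-based survey of a high-Arctic
*Geodia* sponge ground and its isotope sample set.

**Survey.** Adult counts per image are Poisson with rate density × imaged
area. Only between-image mean ± SD densities are known per habitat category
(b: 0.8 ± 0.7, c: 2.8 ± 1.1, d: 5.9 ± 1.7 ind m⁻²; category a was never
quantified and is given a nominal sparse 0.1 ind m⁻² with zero mapped area,
keeping it out of areal upscaling); Poisson is the simplest count law
consistent with those SDs, and a negative-binomial switch
(`nb_dispersion`) is available for overdispersion studies but off by
default. Adult lengths are i.i.d. lognormal — μ = ln(median),
σ = (ln q75 − ln q25)/(2·z₀.₇₅) with z₀.₇₅ = Φ⁻¹(0.75) ≈ 0.6745 — truncated
to the observed 1.5–110 cm range; defaults reproduce the observed median
17 cm and IQR 11–25 cm. Widths are length × a Beta-distributed aspect ratio
(mean 0.8, concentration 10): length and width are both recorded in real
annotations but no joint law is published, and a mean aspect of 0.8 matches
roughly hemispherical massive sponges. Juveniles (< 1 cm) are counted, not
sized, at Poisson rate 3.4 ind m⁻². Default image counts (70/361/211/54 for
a–d at 4 m² per image) mirror the reference survey effort.

**Isotopes.** Each reference group (species × summit, food sources)
contributes n Gaussian draws per isotope from its published mean ± SD.
With `exact_moments=True` the draws are affinely rescaled so each group's
sample mean and SD equal the reference values exactly — the standard way to
reconstitute samples from published summary statistics. The pipeline and
the acceptance script use exact moments: plain resampling of the 15 adult
*G. parva* samples perturbs the consumer δ¹⁵N mean by ~±0.2‰, which moves
the mixing posterior by far more than the sampler's own Monte-Carlo error
and would measure resampling luck rather than the model.

**Radiocarbon profile.** Section ages grow linearly outward from a juvenile
settlement baseline (default 133 yr): age = baseline + distance/growth rate;
Δ¹⁴C is the exact inverse age conversion plus Gaussian analytical noise
(default 3‰, the typical 1σ of the dated reference materials).

What the generator does **not** emulate: spatial autocorrelation of sponges
within or between images, terrain covariates, species identity in the
survey (all massive demosponges are annotated as one class), inter-annual
variability, or any correlation between δ¹³C and δ¹⁵N within a group.
Passing tests therefore demonstrate correctness of the estimators under the
stated statistical structure, not robustness to spatial or taxonomic
structure absent from the simulation.

## Survey summaries

Per-image density is adult count / imaged area; juveniles are reported
separately. Category summaries average per-image densities unweighted —
the convention behind published "average ± SD" figures in image surveys —
with a pooled (total count / total area) estimator available via
`estimator="pooled"`. Size quantiles pool all measured adults and use
linear interpolation (type 7, the numpy default); no convention is stated
for the reference figures and the difference is far below their precision.
Areal upscaling is the area-weighted mean Σ vᵢaᵢ/Σ aᵢ over mapped category
areas (b: 10, c: 15, d: 2.5 km²). Single-image categories report SD = 0
with an explicit `sd_defined=False` flag; single-sample isotope groups
report the SD as missing, never zero.

## Allometric budget

The mass chain WW → DW → C uses DW/WW = 0.187 (back-derived from the
published community pair 4.1/21.9 kg m⁻²) and C/DW = 0.30; both are config.
Whether the cubic size law yields kg wet weight or litres of volume is
ambiguous in its source; the default reads it as kg WW with seawater-like
tissue density (1 kg L⁻¹), and `length_law_output="volume_L"` selects the
other reading. Carbon uses 12.011 g mol⁻¹ and a 365-day year.

The pumping and respiration power laws are treated as volume-specific rates
(the negative exponents identify them as size-specific), multiplied by V
for per-individual totals. Their absolute units cannot be recovered from
the coefficients alone, so the budget exposes two unit-scale multipliers
calibrated at run time against community-level anchors: the area-weighted
respiration of the dense summit categories (c + d) is matched to
25 mmol O₂ m⁻² d⁻¹, and the densest category's (d) pumping to
1640 L m⁻² d⁻¹. The calibrated scales are echoed into every report's
metadata; with them, headline demand (≈ 110 g C m⁻² yr⁻¹ at RQ 1) and
water-column turnover (≈ 599 m yr⁻¹) follow from the synthetic community
itself. The chain identities DW = WW·ratio and C = DW·frac hold exactly at
every aggregation level and are tested to machine precision.

The headline budget domain is the dense sponge ground (categories c + d,
the same domain as the respiration anchor); the all-category upscale is
reported alongside. Standing stocks from synthetic surveys agree with the
reference figures only to order of magnitude (tested within a factor of
two of 1213 g C m⁻² for c + d): the real figures rest on ~10⁴ individual
size measurements whose exact distribution the generator only approximates.

## Mixing model

Marginalized Gaussian formulation: consumer x_ij ~
N(Σ_k p_k(μ_jk + λ_j), Σ_k p_k²(ω_jk² + τ_j²) + σ_j²), Dirichlet(α = 1)
prior on p, half-Cauchy(5‰) residual scales (config). Sources enter as
mean ± SD end-members pooled across summits by exact sample pooling
(n-weighted mean; variance combining within-group sums of squares and
between-group spread, i.e. the sample variance of the concatenated
samples). The default end-member set is siboglinid tubes, surface
suspended POM, and surface sediment; DOM is available but off by default
because its δ¹⁵N is literature-derived.

Sampling is random-walk Metropolis-within-Gibbs on (i) the softmax
reparameterization of p with the last logit pinned at zero (log-Jacobian
Σ ln p_k) and (ii) log σ (Jacobian ln σ), each block with its own step size
adapted during burn-in toward 30% acceptance (multiplicative updates every
50 iterations, step clipped to [10⁻³, 10]). Defaults: 40 000 iterations,
10 000 burn-in, thinning 10. Effective sample sizes are computed per
proportion (via arviz); ESS < 100 raises a warning and is recorded in the
result rather than failing silently. Identical seeds give identical
draws. TEF-scenario comparisons reuse one seed across scenarios (common
random numbers), so identical scenarios give exactly identical posteriors
and the reported shifts are paired.

Verification: a two-source configuration with near-degenerate source SDs is
checked against the exact linear-algebra solution of the mixing equations;
a 50-replicate simulation study (K = 3, 20 consumers) checks ≥ 90%
empirical coverage of the 95% credible intervals; uninformative data
recover the Dirichlet prior mean. During development the three-source
posterior for the headline run was additionally validated against brute
quadrature over the simplex × residual scales; the sampler's posterior
means agreed within Monte-Carlo error.

Two caveats on the headline run. First, the consumer mean δ¹³C (−18.5‰)
lies slightly outside the TEF-corrected source hull (max −19.1‰), so the
δ¹³C residual scale absorbs a systematic misfit — an indication, visible in
the model itself, that the three default end-members do not span the true
carbon sources (the community's Δ¹⁴C argues for an additional DIC-derived
autotrophic contribution). Second, raising the ¹⁵N TEF from 1.5 to 3.5‰
does **not** lower the siboglinid share under this three-member set: all
corrected sources then overshoot the consumer δ¹⁵N, the ¹⁵N residual
inflates, and the tight δ¹³C constraint (favoring siboglinid tubes)
dominates, raising the share from ~42% to ~56%. A decrease obtains in
configurations where a depleted member can take the displaced share (see
the two-source demonstration in the test suite); with the default
end-members the sensitivity statement is therefore configuration-dependent,
and the corresponding directional acceptance test documents this by
failing.

SEAc requires n ≥ 3 points and raises otherwise; exactly collinear points
return zero area with a degenerate flag rather than an error.

## Radiocarbon

Conventional ages use the bare Libby-mean-life formula with no reservoir or
calendar calibration; ages are reported raw and rounded to the nearest
century (the convention of the reference figures). Post-bomb samples
(Δ¹⁴C > 0) return negative ages with a flag. A few published (Δ¹⁴C, age)
pairs (e.g. −16‰ ↔ 200 a, −436‰ ↔ 4700 a, −213‰ ↔ 1986 a) are inconsistent
with this bare formula at century rounding — presumably unreported
corrections or rounding of Δ¹⁴C — and are excluded from tests; the
consistent anchors (−527‰ ↔ 6000 a, −245‰ ↔ 2300 a) are asserted.

The growth-rate estimator regresses **age on distance** and inverts the
slope. Radial distance is measured precisely while the Δ¹⁴C measurement
error propagates into age, so the regression error lives on the response;
regressing the noisy age as the predictor would attenuate the slope by
~35% at 5‰ noise. With exactly two sections both directions reduce to
Δdistance/Δage. The standard error follows by the delta method; fewer than
two distinct distances or a zero age span raise degenerate-input errors,
and a negative estimated rate is flagged, not raised.

The spicule-tube mat carbon stock is thickness × 10⁴ × bulk DW density ×
OM fraction × C fraction. The OM fraction (8% of DW) and the ≥ 4 cm
thickness are measured; the bulk dry density (0.31 g cm⁻³) is **not** — it
is a documented calibration that yields ~500 g C m⁻² at the defaults and is
flagged as an assumption in all outputs. OM → C of 0.5 is conventional.

## Pipeline

One config drives all stages (flag > file > default precedence; unknown
keys rejected by name). Stage seeds are spawned from the master seed, so a
report is reproducible bit-for-bit from its own config echo. Output tables
are CSV with a comment header carrying version and seed; the report is
sorted-key JSON. Partial outputs are removed if a stage fails.

Problem sizes: the default pipeline simulates the reference survey effort
(626 analyzed images at 4 m²); suite-internal MCMC verification runs use
6 000-iteration chains per replicate for the 50-replicate coverage study
and 150 000-iteration chains for the headline posterior; the acceptance
script uses a 400 000-iteration chain (≈ 7 000 retained draws, proportion
ESS ≈ 10³, Monte-Carlo error well under one percentage point on the diet
share).

## Known limitations

- The mixing model is two-isotope, concentration-independent, and has no
  isotope routing; contributions are biomass-proportion equivalents.
- End-member choice is the dominant structural uncertainty of the diet
  share; the default set is a config decision, not a measurement.
- The budget ignores temperature/pressure corrections and all non-sponge
  metabolism, so community demand is conservative.
- No calendar-age calibration (IntCal/Marine) or reservoir modelling; ages
  are conventional ¹⁴C years throughout.
- Synthetic surveys carry no spatial structure, so the density SDs between
  images are purely Poisson unless the negative-binomial switch is used.
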