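# Methods

This note documents the models implemented in `dairyshed`, their
assumptions, the parameter defaults that matter, and the design choices
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Forest attribution

Net forest C loss (kg C ha⁻¹ yr⁻¹, annual rates; a cumulative layer can be
annualised with `period_years`) is reduced to the component attributable to
dairy-cattle grazing in four steps, in this order: (1) restrict to natural
forest (forest mask minus plantations); (2) set burnt pixels to **nodata**
rather than zero, so fire-affected pixels drop out of both the loss sums and
the area denominators — fire losses can be neither attributed to cattle nor
mitigated by feeding; (3) subtract the nonrenewable-biomass fuelwood layer,
clamping at zero per pixel because a negative grazing-attributed loss is
physically meaningless where fuelwood extraction exceeds the net signal;
(4) multiply by the county's dairy proportion of the cattle herd
(pixel-centre county lookup; an uncovered pixel is an error, not a silent
skip).

Variance propagates through the subtraction as
`var(A−B) = var(A) + var(B) − 2 cov(A,B)`, floored at zero against round-off
and validated against the Cauchy–Schwarz bound. The input layers carry
*relative* SDs; the covariance defaults to 0 and is exposed as a parameter
because no estimation rule for it is fixed by the data model. The county
scaling multiplies the variance by the squared proportion. All internal
rasters stay in kg C ha⁻¹ yr⁻¹; the 44/12 C→CO₂ conversion is applied only
when reporting study-area totals (Mg CO₂eq yr⁻¹ = Σ value × ha × 44/12 /
1000). Study-area SDs assume independent pixels.

Raster convention: pixel-is-area, origin top-left, row-major, all layers on
exactly one shared grid — no resampling happens inside the analysis;
producing co-registered 1-km² inputs is the generator's (or an ingestor's)
job.

## Herd model and Tier-2 emissions

Emission kernels follow the IPCC Tier-2 inventory forms:

* enteric CH₄ = GE × Ym / 55.65, with GE the gross energy intake
  (Σ intake × 18.45 MJ/kg DM) and Ym defaulting to 0.065 (range
  0.055–0.075);
* manure CH₄ = VS × B₀ × 0.67 × Σ split × MCF, with VS the undigested dry
  matter less 8% ash, B₀ = 0.13 m³/kg VS (0.10–0.24), MCF 0.01 on pasture
  and 0.04 on heaps;
* N₂O: intake N = Σ intake × CP/6.25; excreted N = intake − milk N
  (0.53% of FPCM) − retained N. Pasture-deposited N goes to the *soil*
  category (direct EF 0.02 plus volatilisation and leaching pathways), heap
  N to the *manure-management* category (direct EF 0.005 plus
  volatilisation), fertilizer N to its own category (EF₁ 0.01 plus both
  indirect pathways); each direct/indirect term is N × EF × 44/28 × GWP.

GWP₁₀₀ defaults are CH₄ = 25 and N₂O = 298 (the AR4 values used by national
inventories of the study period), overridable. The manure split defaults to
70% pasture / 30% heap; scenarios that reduce grazing (FoCo, FoFeCo) shift
0.3 from pasture to heap. Emissions from fertilizer manufacture and
transport are excluded. All emissions are allocated to milk (no milk/meat
allocation). The concentrate production factor (kg CO₂eq per kg
concentrate) has no authoritative value in the data model; it ships as a
documented placeholder (0.30, range 0.20–0.40) that users must set for
absolute concentrate accounting, and it is excluded from the exact
acceptance checks.

Milk output is an annualised energy-balance surrogate of a lifetime
(13-year) dairy-cow simulation: metabolisable energy (0.81 × digestible
energy) minus maintenance (0.386 MJ NEₘ per kg⁰·⁷⁵ per day at 400 kg mature
weight, k_m = 0.70) and a 10% pregnancy overhead is converted to lactation
net energy (k_l = 0.60) and divided by the energy content of milk
(1.47 + 0.40 × fat%), with a crude-protein ceiling (25% of CP intake can
become milk protein) and averaging over the 10 productive of 13 lifetime
years. FPCM = raw × (0.337 + 0.116 × fat% + 0.06 × protein%), defaults
4.0% fat / 3.3% protein. The surrogate is monotone in diet energy and
digestibility and is used for direction properties; a **calibration table**
of observed per-system yields (the built-in diet table) overrides it in
scenario accounting, so downstream arithmetic runs on measured yields even
where the surrogate deviates. A full stochastic herd-demography model is
deliberately out of scope.

Uncertainty is one-at-a-time: for the baseline, each parameter is Latin-
hypercube sampled uniformly over its (min, max) while all others sit at
their means; for scenarios, each parameter is evaluated at its minimum and
maximum only, contributing half the output range as an SD. Per-parameter SD
contributions combine in quadrature (no combination rule is canonical for
one-at-a-time designs; quadrature is exact for independent linear effects).

## Land budget and yield-gap closure

Per pixel, cropland demand is Σ over cultivated feeds of
heads × intake / yield (Napier at 12 t DM/ha; silage maize at the level's
yield). Pasture grass is grazed from existing grassland and maize stover is
a crop residue, so neither adds demand. Only the demand **additional to the
baseline diet** drives land conversion, and only existing grazing land is
convertible; the grazing land actually converted per pixel is
min(extra demand, available). Deficit pixels (extra demand > available) are
dissolved into 8-connected polygons (fewer, larger polygons — conservative
in the sense of flagging more forest as at risk) and buffered by 5 km, the
empirically motivated farm-neighbourhood radius. Forest pixels whose
centres intersect a buffered polygon retain their grazing-attributed loss;
the rest is mitigated. Pixel–polygon membership is by pixel centre
throughout.

Maize yield-gap defaults: actual yield Ya = 1.6 t DM/ha against a
water-limited potential Yw = 7.0 t DM/ha (Ya ≈ 23% of Yw, inside the
30–82% yield-gap range reported for the region); the levels Yw50/Yw80
realise 50%/80% of Yw. Above-ground N uptake is 14 kg N per t DM, and the
fertilizer requirement is the *extra* uptake over Ya divided by a 33%
fertilizer-N use efficiency (manure N at 20% NUE when a manure share is
configured), giving ≈ 81 (Yw50) and ≈ 170 (Yw80) kg N/ha. Grazing-to-
cropland conversion is priced at 36.7 Mg CO₂eq/ha (range 22–51, a
grassland→cropland soil-carbon loss) and annualised over a 20-year
amortisation period — the convention is configurable since none is fixed by
the accounting frame.

The concentrate land footprint is a separate, aspatial account: national
ingredient yields (27% rice bran, 4% lime, 27% wheat, 27% maize, 5%
sunflower cake, 10% cotton-seed cake) convert the scenario's concentrate
tonnage into hectares, minus the hectares already allocated to the baseline
tonnage. It is reported as a carbon-leakage indicator (worst case: cleared
from secondary forest at 112.7 ± 3.9 Mg CO₂eq/ha) and never added to the
spatial budget or the combined total. The per-system baseline concentrate
tonnages in the population table are reported fixtures, not derivable from
per-head baseline intakes; scenario tonnages are computed (productive cows ×
450 or 900 kg, i.e. 3 or 6 kg/day over 150 early-lactation days).

## Scenario engine

A scenario × yield level runs herd, land and forest stages and aggregates
with productive cows (60% of the dairy population) as weights. The combined
AFOLU total debits retained forest loss and credits forest C gain as a
signed term; emission intensity is reported both with and without the
forest term. Percentage deltas use the baseline as denominator. Two
intensity-delta conventions are emitted: the aggregate ratio of
production-weighted intensities, and per-LPS pairings — with the built-in
tables the aggregate baseline intensity is 2.36 and FoCo's 1.68 kg CO₂eq/kg
FPCM, a 28.8% aggregate reduction, while the per-LPS pairing reaches −33%
(e.g. 2.64 → 1.76 in the rainfed-arid system).

## Synthetic landscape and survey

The generator emulates the statistical structure the analysis assumes, not
any real geography. Spatially autocorrelated fields are Gaussian-filtered
white noise (σ = 2 pixels, configurable), so forest (25% of a 60×60 km
grid by default) forms contiguous patches and land deficits cluster.
Carbon fields use means of 2,000 (net loss), 1,500 (gain) and 500 (NRB)
kg C ha⁻¹ yr⁻¹ with 30% relative SD — magnitudes in the range of the
region's farm-neighbourhood statistics. NRB is generated as a smooth
fraction of the loss field, so fuelwood never exceeds net loss pointwise.
Cattle density (20–150 head/km², ×1.5 within 5 km of forest edges) and
grazing land (10–70 ha per 100-ha pixel) put most pixels in surplus with
deficits as localised exceptions near forests — the regime in which the
deficit mechanism is meaningful; where real deficits sit relative to
forests is not fixed by the data model, so the edge parameters are exposed
rather than hard-coded. Counties are a Voronoi partition of random seeds
(only a zonal overlay is needed) with dairy proportions uniform in
0.5–0.95; the six livestock-production-system classes are nearest-centre
partitions. One global seed drives named substreams (CRC-keyed child
generators), making every bundle bit-reproducible.

The farm survey uses a Gaussian copula: a latent forest-loss factor plus
one latent per indicator, correlated at 2·sin(πρ/6) so the *rank*
(Spearman) correlation hits the target; only rank structure is asserted, so
marginals are free (Poisson herd sizes, lognormal milk, beta fractions,
gamma areas). A non-positive-semidefinite request errors. Farms are placed
on near-forest pixels by **rank matching**: candidate sites are ranked by
their measured 5-km neighbourhood mean of attributed loss and matched to
the farms' latent-loss ranks, so zonal statistics computed later recover
the requested correlations up to copula sampling noise (Spearman SE ≈ 0.07
at n = 216; recovery tests therefore compare the Monte-Carlo mean over 10
replicates against a ±0.1 band). Intensified farms are the top third of
combined milk/fodder ranks, guaranteeing the type contrast by construction.

What passing tests on this generator do **not** show: agreement with the
real remote-sensing stack, survey-derived means, or absolute study-area
totals — those depend on the original data. What they do show: the
attribution algebra, the Tier-2 kernels, the printed-table arithmetic
chain, the direction and monotonicity of every mechanism (yield-gap
closure → less demand → fewer deficits → less retained forest loss; LUC
savings exceeding the fertilizer N₂O increase), and the recoverability of
the assumed farm–forest correlation structure.

## Numerical choices and problem sizes

Double precision throughout; rounding to integer tonnes/hectares only at
report time. Variances floored at 0 against round-off. Buffers use 32
quadrant segments so circular areas are exact to ~2·10⁻⁴. Degenerate
parameter ranges contribute zero variance rather than erroring. The test
suite and acceptance script run the monotonicity sweep on 100 seeds of a
32×32 landscape and the survey round trip on 10 replicates of 216 farms on
a 60×60 landscape — sizes chosen as the smallest at which the spatial
mechanisms (multi-pixel deficit polygons, 5-pixel buffers) are
non-degenerate.

## Known limitations

No animal disease, reproduction failure, market dynamics or daily
weather-driven feed availability; no fire-spread modelling or time-series
change detection; no economic feasibility analysis of fertilizer use. The
LUC amortisation convention and the covariance in the variance propagation
are user choices with defaults, not estimated quantities. Study-area SD
aggregation assumes pixel independence, which understates spatially
correlated uncertainty.
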