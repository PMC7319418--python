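# Methods

This note documents the models, the numerical choices, and what the
synthetic test data do and do not establish.

## Forage index

Each landcover source carries a suitability table (``data/suitability.yaml``)
mapping class labels (or percent-cover bands) to integers 0–5. The shipped
tables cover the headline classes of the four national-dataset analogues
(fine categorical vector, categorical raster, percent tree-cover raster,
woody linear features); they are deliberately user-extensible because full
national class lists are far longer. Percent bands are stored half-open and
contiguous — the printed source bands leave small gaps (e.g. 3–4%) which we
close so every percentage maps to a value.

Compositing follows a priority-then-maximum rule: the high-resolution
categorical vector source is the single priority layer (configurable), the
maximum of the remaining coincident layers fills its gaps, and cells with no
data in any source score 0 ("no vegetation"). This makes the index defined
catchment-wide, which the downstream reach summaries require. Compositing is
idempotent and never returns less than the priority value where the priority
layer is defined.

Reach summaries use the mean of the top 50% of cells — ceil(k/2) cells, so
single-cell samples are defined — inside a buffer of (channel half-width +
10 m or 40 m) around the reach extended 100 m up- and downstream. The
extension walks the network graph (not a Euclidean line), truncating at
headwaters and the outlet; an empty sample returns 0 with a warning.
Rasterisation is cell-centre-in-polygon; linear features are buffered by
half a cell first; resampling of coarser rasters is nearest-neighbour to
preserve class values.

## Terrain

Routing runs on the stream-burned DTM (network cells lowered 30 m; the
operation is deliberately not idempotent and the pipeline calls it once).
Depressions are removed by priority-flood filling with an epsilon gradient,
which also resolves flats deterministically; D8 directions are
steepest-descent with off-grid drainage only where no on-grid neighbour is
lower. Reach slope is read from the *unburned* DTM as |Δz|/length with a
0.0001 floor — burned elevations or signed slopes would corrupt stream power
and the inference stages. Contributing area is the maximum accumulation
among a reach's cells times the cell area.

Strahler orders are computed on the accumulation-thresholded raster stream,
with the threshold chosen so the raster stream length matches the vector
network within 10%. Burned national DTMs typically inflate raster orders by
one (parallel flow paths hug the burned channel) and scatter spurious
order-1 filaments along channel edges; `strahler_with_correction` therefore
decrements orders above 1 (default 1) and discards order-1 cells off the
vector network. The synthetic terrain is constructed cleanly enough that no
inflation occurs, so the synthetic pipeline runs with decrement 0 and with
the stream definition restricted to the network (a stronger form of the
same edge-filament pruning); on real burned DTMs the artifact-correction defaults
apply. Per-reach order assignment trims roughly half a cell from each reach
end so a tributary does not read the incremented order of the junction cell
it merely touches. The raster orders are verified against an independent
graph-based Strahler computation on the vector network across ten random
synthetic catchments.

## Hydrology

Exceedance discharges use linear interpolation between order statistics:
Q_p is the (100−p)th percentile of the daily series (p = 2 high flow, 80 low
flow), requiring at least 30 daily values (a warning below one year). The
rating model is the standard hydrological scaling law Q = a·Area^b, fitted
by non-linear least squares started from the log-log linear estimate; two
gauges interpolate exactly, identical areas are rejected as unidentifiable.
Stream power is Ω = ρ g Q S in watts with ρ = 1000 kg/m³ and g = 9.8 m/s².

## Fuzzy inference

Both capacity stages are classic Mamdani systems: trapezoidal memberships,
rule firing by the minimum over antecedent memberships, per-consequent-term
aggregation by maximum, centroid defuzzification over the consequent
universe [0, 30] dams/km discretised at 0.01. Rule-base coverage is
validated twice: every variable's memberships must cover its universe, and
evaluation raises if no rule fires.

The published rule lists and membership breakpoints for the two stages are
in supplementary material that is not redistributable, so the shipped
defaults (``data/fis_vegetation.yaml``, ``data/fis_combined.yaml``) are
adapted from the BRAT dam-capacity framework the approach extends: five
forage terms per vegetation antecedent, a 25-rule vegetation stage, and a
combined stage whose 240-rule base is the full antecedent cross product
generated from a degradation table (severe slope or stream power lowers the
vegetation capacity class; a Q2 "blowout" regime caps the result at Rare;
slope beyond ~0.17–0.23 or absent vegetation forces None). Both files are
plain YAML so the original rule lists can be dropped in verbatim. Because
the defaults are package choices rather than published values, the tests
assert FIS *mechanics* (agreement with an independent brute-force evaluator
to 0.05 dams/km, monotone response directions, universe bounds), not
specific per-reach capacities.

Centroid defuzzification of min–max aggregates is piecewise-smooth but not
strictly monotone: at crossovers of adjacent terms that share a consequent,
the output dips by up to ~0.01 dams/km (the usual "scallop"). The
monotonicity tests allow 0.02 dams/km of slack for this.

A defuzzified Mamdani output can never be exactly 0, but the capacity
classes define None as exactly zero. The pipeline therefore snaps outputs
below 0.25 dams/km — the lower half of the "none" consequent band, reachable
only when the none term dominates — to 0 before constraints and
categorisation. Constraint post-processing never increases capacity. The
printed class bands leave (4, 5) unassigned; the implemented intervals are
half-open (None {0}, Rare (0,1], Occasional (1,4], Frequent (4,15],
Pervasive (15,30]) so every value has exactly one class.

## Bayesian validation

With a uniform prior the per-category binomial posterior is exactly
Beta(k+1, n−k+1); we use the closed form (MAP = k/n, equal-tailed 95%
quantile intervals, HPD available via a config switch) rather than an MCMC
sampler, and cross-check against a seeded Metropolis chain in tests. Category
contrasts are summarised from Monte-Carlo draws of the posterior ratio
pᵢ/pⱼ. The reported "MAP Bayes factor" is the mode of a Silverman-bandwidth
KDE of the **log** ratio, exponentiated: the log-scale mode is
reciprocal-symmetric (BF(i,j) = 1/BF(j,i)) and avoids the strong downward
pull of the linear-scale mode of a right-skewed ratio (for Beta(21,81) vs
Beta(11,91) the analytic linear-scale mode is 1.69 while the log-scale mode
is 1.905, consistent with the intuitive ≈2). A zero-success denominator is
flagged as having an unbounded upper interval.

## Dam counts

Overdispersion is tested with the Cameron–Trivedi auxiliary regression of
((y−μ̂)² − y)/μ̂ on μ̂ (no intercept) after a Poisson fit, one-sided against
Var = μ + α·μ²; its size and power are verified by simulation (≤8% type-I
at the 5% level on Poisson data, ≥95% power at α = 1, n = 2000).

The ZINB uses the modelled maximum dams per reach as the covariate in both
components; the zero-component covariate is a package choice (the source
framework names only the count covariate) and is configurable. statsmodels'
default ZINB start values diverge on zero-heavy data, so fitting warm-starts
from NB and logit fits, runs Nelder–Mead into the basin, polishes with BFGS,
and keeps the best optimum that converges with finite standard errors;
bootstrap and cross-validation refits warm-start from the parent fit.
Predictions are (1−π̂)·μ̂ per reach under the all-reaches-active scenario,
with 95% percentile intervals from a case-resampling bootstrap (replicates
that fail to converge are dropped and counted; more than 10% dropped is an
error). Cross-validation repeats 70/30 splits, sub-samples the test set at
every percentile of its size, and pools a zero-intercept regression slope,
RMSE and MAE of summed predictions versus summed observations.

One caveat found during development: summed predictions over *random*
subsets track subset size, so even a covariate-free model attains a pooled
slope near 1 — the cross-validation slope validates calibration of totals,
not per-reach discrimination. The negative-control test therefore checks
per-reach prediction/observation correlation instead.

## Synthetic data

The generator is deliberately constructed rather than physically simulated:
a channel tree (main stem with perpendicular tributaries, vertices one cell
apart) with strictly decreasing vertex elevations, hillslopes rising with
distance from the nearest channel point plus a parabolic valley-side term,
channel polygons widening downstream, landcover mosaics allocated to 50 m
riparian chunks by seeded proportional assignment, gauge flows lognormal
about Q = 0.05·Area^0.8 (σ = 0.3 by default, two years of daily values),
and observations drawn from monotone activity logits per forage category
(active probabilities ≈ 0.05 → 0.73 from unsuitable to preferred) with
dams from a ZINB with zero-inflation logit 1.0 − 0.9·x, count log-mean
−1.2 + 0.55·x and dispersion α = 0.6 on x = maximum dams per reach
(Gamma(1.5, 1.0), truncated at 6). Everything derives from one seed through
separate named streams and is bit-identical across runs.

What this emulates: the geometric and topological structure the pipeline
must handle (confluences, widths, orders, buffers), known-parameter recovery
for the statistical stages, and survey-scale zero-heavy count data. What it
does not emulate: real hydrographs and climate forcing, spatial
autocorrelation of landcover and of beaver behaviour, territory dynamics,
GPS snapping error, or the class richness of national landcover products.
Passing tests therefore establish correctness of the computations and
well-calibrated statistics under the stated generative conditions, not
field validity of the default fuzzy rule sets.

Problem sizes used by the default test run and the acceptance script:
catchments up to 96×96 cells at 5 m, 2104-reach survey-scale simulations
(matching the published number of active reaches), 100 recovery replicates
at n = 5000 for ZINB coverage, 200 replicates at n = 2000 per arm for the
dispersion test, and 200 bootstrap replicates for prediction intervals.

The published survey-summary table ships verbatim as
``data/table4_survey_summary.csv`` for reporting-arithmetic checks. The per-reach data behind that
published summary are not public, so
``data/synthetic_survey_dams.csv`` is a synthetic stand-in constructed to
match every published tally (89 dams in 58 reaches; 41/35/13 per site;
per-category dam counts; 39 frequent-or-pervasive dammed reaches).

## Known limitations

- The default fuzzy rule sets are framework-faithful stand-ins, not the
  published supplementary rules; conclusions about absolute capacities
  depend on them.
- Removed/collapsed dams count toward reach activity but are excluded from
  dam counts; whether the source analysis included them is unstated.
- No geographic coordinate support: all layers must share one planar metric
  frame.
- The D8/priority-flood choices are standard but not stated in the source;
  both, like the burn depth, slope floor, and stream threshold, are
  config-exposed.
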