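# Methods

## The ISAR and its estimation

For a target species *t* in a fully mapped community, the individual
species–area relationship is the mean number of other species within
distance *r* of the individuals of *t*:

    ISAR_t(r) = Σ_{j≠t} D_tj(r),

with `D_tj(r)` the cumulative nearest-neighbor distribution function — the
proportion of *t*-individuals whose nearest *j*-individual lies within *r*.
Conspecifics never contribute. Distances are planar Euclidean and "within"
means the closed disc (≤ r). The default radius grid is 1–50 m at 1 m
steps.

**No edge correction.** Bivariate patterns of two species need not be
homogeneous, which undermines the standard corrections; and since observed
and simulated curves are computed with the identical estimator, the small
bias from focal individuals near the border cancels in the comparison.
Focal individuals near the border are therefore retained.

**Computation.** The defining computation is exhaustive: per-target,
per-species nearest-neighbor distances, reduced to per-radius species
counts. The implementation groups the (fixed) heterospecific neighbor pool
by species and takes segmented minima over a dense distance matrix,
switching to per-species k-d trees when the pair count would exceed ~2×10⁷
(memory, not speed, is the binding constraint). Counts are integers, so
the result is bit-identical to the brute-force per-disc census — the unit
and acceptance suites assert exact equality, not approximate.

## Size stratification and target selection

Stems are adults when DBH > 10 cm and saplings when 1 ≤ DBH ≤ 10 cm; a stem
at exactly the threshold is a sapling (the sapling class is the closed
interval). Target species are those with abundance *strictly* above 50,
counted on adults by default because the focal individuals of the main
analysis are adults; the basis is configurable (`basis="all"`). Ranks are
assigned by descending abundance with lexicographic species-code
tie-breaks, so reports are deterministic. Three analysis modes share one
code path: `large_large` (adult targets, heterospecific adult neighbors),
`large_small` (adult targets, heterospecific sapling neighbors), and `all`
(no size restriction, for unmarked data).

## Null models

Both models relocate only the focal individuals of the target species;
every other stem keeps its mapped coordinates exactly.

**Homogeneous Poisson.** Focal individuals are redistributed i.i.d.
uniformly over the window. The resulting reference is the plot-wide
species–area relationship; departures may reflect habitat association,
interactions, or both.

**Heterogeneous Poisson.** Focal individuals are redistributed according to
a kernel estimate of the species' own intensity λ_t(x): an Epanechnikov
kernel k_R(d) ∝ max(0, 1 − (d/R)²) with radius R = 50 m, summed over the
observed focal locations on a 5 m cell grid and renormalized so that the
surface mass equals the focal count (no kernel mass is lost over the
border, keeping the conditional simulation exact). Replicates draw each
point independently with cell probabilities ∝ λ × cell area, uniformly
within the chosen cell — an inhomogeneous Poisson process conditioned on
the observed abundance. Two readings of "local redistribution" exist
(kernel-intensity sampling vs per-individual displacement within R);
kernel-intensity sampling is adopted here because it is the estimator the
moving-window formulation describes, and R then plays the role of the
maximum redistribution radius. Kernel form, R, and cell size are all
configurable; `bandwidth_sweep` reports label stability across R (30/50/70
m is the conventional sensitivity sweep).

The model embodies the **separation-of-scales** assumption: habitat
association acts above R, individual interactions below it. With R = 50 m
the null preserves habitat structure at > 50 m scales and randomizes
everything smaller, so its departures are attributable to interactions —
*if* the assumption holds. The habitat scenarios of the synthetic module
place all covariate structure at ≥ 100 m length scales, so the assumption
holds by construction there; on real data it is an assumption, not a fact,
and the bandwidth sweep is the diagnostic.

Discretization: results must be (and are, by test) stable under halving
the 5 m cell size; 5 m is a 10:1 ratio to the default bandwidth, fine
enough that within-cell uniformity is negligible against a 50 m kernel.

## Monte Carlo inference

Each species gets `n_sim = 199` simulations. Reproducibility is by keyed
RNG substreams — one stream per (master seed, species code, simulation
index) via `SeedSequence` — so evaluation order, parallelism, or skipping a
species cannot change a single coordinate elsewhere.

**Pointwise envelopes.** At each radius the band spans the 5th-smallest to
5th-largest simulated value (k = 5 of 199; the observed value falls outside
with probability 2k/(n_sim+1) = 0.05 under the null). Envelopes are
per-radius diagnostics; they are not corrected for simultaneous inference
across radii, which is what the interval test is for.

**Interval goodness-of-fit rank test.** For curves Ĥ_i (i = 0 observed,
1..199 simulated) and an interval I,

    u_i = Σ_{r∈I} (Ĥ_i(r) − H̄_i(r))²,

where H̄_i is the mean of all curves *except* the i-th. The leave-one-out
mean makes the u_i exchangeable under the null, so the ascending rank of
u_0 among all 200 is uniform; the test rejects at level α when
rank > (1−α)(n_sim+1) — rank > 190 at α = 0.05. Ties assign the observed
statistic the smallest rank of its tie group (conservative). The five
default intervals 1–10, 11–20, 21–30, 31–40, 41–50 m tile the radius grid;
pooling radii into intervals is the multiple-testing control — no further
correction is applied across species or intervals.

**Direction and labels.** u is sign-blind, so the direction of a
significant departure is the sign of Σ_{r∈I}(Ĥ_0 − H̄_0); mixed-sign
intervals resolve by that sum, and a significant result with an exactly
zero sum is reported as a degenerate-classification error rather than
silently labeled. Significant positive / significant negative / otherwise
map to accumulator / repeller / no_effect under the heterogeneous null and
positive / negative / none under the homogeneous null. Note the ISAR is
cumulative in r, so an interaction at distance d also lifts intervals just
above d until local richness saturates; interval labels localize the
*signal*, not the mechanism boundary.

## Synthetic communities

The generator supplies the study conditions for validation:

* **CSR** — exact per-species counts, i.i.d. uniform; the null case.
* **Habitat** — intensity ∝ exp(β_s z(x)) with z a sum of three Gaussian
  bumps of 100 m length scale on a 500 × 500 m window (scaled to [0, 1]);
  β = 0 reduces exactly to CSR. Sampling is by rejection, so counts are
  exact.
* **Thomas** — within-species clustering: uniform parents, Gaussian
  offspring displacement, conditioned on the species count.
* **Interaction overlays** — accumulator: `round(strength ×
  recruits_per_target × n_targets)` heterospecific recruits placed
  uniformly in the d_int-disc of randomly chosen focal individuals, species
  drawn uniformly from the non-target codes (so no single species'
  abundance rank is confounded), sapling DBH by default (the
  Janzen–Connell reading: adults accumulate heterospecific juveniles).
  Recruit seeding is preferred over relocating targets into rich areas
  because it creates the signal at a *known* distance, giving a crisp
  recovery test. Repeller: heterospecific stems within d_int of any focal
  individual deleted independently with probability `strength`; stems
  farther than d_int are never touched (asserted by set difference).
* **DBH marks** — dbh = 1 + Lognormal(μ, σ) with μ solved so that
  P(dbh > 10) equals `adult_fraction` exactly; the default 0.16 echoes the
  roughly one-adult-per-six-stems structure of mapped subtropical forest
  censuses, σ = 1 gives a realistic right-skewed size distribution.

What the generator does *not* emulate: demographic dynamics, dispersal
kernels, species–abundance distributions fitted to any particular plot,
small-scale (< 50 m) habitat variation, or correlated marks (size–habitat
interactions). Passing tests therefore demonstrate calibration and power
of the *inference machinery* under controlled truth — not that any
particular field pattern is an interaction.

## Validation summary (all computed by the test suite)

* Exact oracle equivalence of the ISAR estimator with an exhaustive
  per-disc census on random communities up to 500 stems.
* Type-I error of the 1–10 m GoF test on truly-CSR data ≈ α (200
  replicates, exact binomial 99% tolerance around 0.05); envelope
  containment at a fixed radius ≈ 95% on the same replicates.
* Critical rank at α = 0.05, n_sim = 199 is exactly 190 (closed form).
* Planted accumulators (d_int = 10 m, strength 1) are recovered on 1–10 m
  and labeled no-effect on 41–50 m, and planted repellers recovered on
  1–10 m, in ≥ 80% of 50 replicates each.
* Habitat-only scenarios yield strictly more positive labels under the
  homogeneous than accumulator labels under the heterogeneous null in
  every replicate (the separation-of-scales contrast).
* With a flat intensity surface the heterogeneous null reproduces
  homogeneous-null labels on ~98% of species × interval cells.

Problem sizes in the routine suite (10 species × 60 stems for calibration,
12 × 250 for recovery, 8 × 120 for the habitat contrast) were chosen as the
smallest communities at which the respective effects are comfortably
detectable; the same code paths scale to full plot censuses (tens of
species, 10⁵ stems), where the per-species k-d tree path bounds memory.

## Known limitations

* The heterogeneous null conditions on the observed abundance and
  intensity of the target itself; a species that is rare *because* of
  interactions partially absorbs its own signal into the surface.
* Interval labels inherit the cumulative nature of ISAR (see above).
* The GoF direction is a net summary; an interval where positive and
  negative deviations cancel can be significant by u yet directionally
  ambiguous — the summed-deviation rule resolves it, by fiat.
* No phylogenetic or functional weighting of richness, and no
  torus-translation or pattern-reconstruction nulls.
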