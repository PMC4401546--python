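# isarpipe

Individual species–area relationships (ISAR) for fully mapped plant
communities: neighborhood species richness around the individuals of target
species, tested against homogeneous and heterogeneous Poisson null models
with Monte Carlo envelopes and an accumulated-deviation goodness-of-fit
test, yielding per-distance-interval **accumulator / repeller / no-effect**
classifications.

## Who this is for

Spatial community ecologists working with forest-dynamics-plot style
censuses — one record per stem with species code, planar coordinates and
DBH — who want a "plant's-eye" view of diversity: does a given species sit
in neighborhoods that are richer or poorer in species than chance predicts,
at which distances, and is that driven by individual interactions or by
habitat association?

## The statistic

For a target species *t*, the individual species–area relationship is

```
ISAR_t(r) = Σ_{j≠t} D_tj(r)
```

where `D_tj(r)` is the proportion of individuals of *t* whose nearest
individual of species *j* lies within Euclidean distance *r* (closed disc,
no edge correction). Equivalently, `ISAR_t(r)` is the mean number of other
species found within radius *r* of the individuals of *t*. Curves are
evaluated on a 1–50 m grid at 1 m steps by default.

Two null models relocate only the target individuals (all other stems stay
fixed):

* **homogeneous Poisson** — uniform relocation over the window; deviations
  measure departure from the plot-wide species–area relationship, whatever
  the cause;
* **heterogeneous Poisson** — relocation according to a kernel estimate of
  the species' own intensity surface (Epanechnikov kernel, 50 m radius, 5 m
  cells by default), which preserves habitat association at scales above
  the kernel radius and randomizes structure below it. Under this
  *separation of scales* assumption its deviations isolate individual
  interactions.

Significance uses 199 Monte Carlo simulations per species: pointwise 95%
envelopes (5th-lowest / 5th-highest simulated value at each radius), and
per distance interval (1–10, …, 41–50 m) the goodness-of-fit statistic
`u_i = Σ_r (Ĥ_i(r) − H̄_i(r))²` with leave-one-out ensemble means; the test
rejects at α = 0.05 when the observed `u_0` ranks above 190 among all 200
values. Significant positive deviations under the heterogeneous null are
accumulators, negative ones repellers.

Because real censuses of this kind are typically access-restricted, the
package ships a first-class synthetic-community module (CSR, Thomas
clustering, smooth habitat gradients, and constructed accumulator/repeller
overlays with a known interaction distance) so that every inference stage
can be validated against ground truth.

## Worked example

Plant a strong accumulator — heterospecific saplings seeded within 10 m of
the adults of `sp001` — and ask the heterogeneous null whether it finds it:

```python
from isarpipe import (
    DistanceInterval, RadiusGrid, ScenarioConfig, Window,
    classify_species, default_intervals, generate_community,
    gof_rank_test, run_null_ensemble,
)

scenario = ScenarioConfig(
    window=Window(0, 250, 0, 250), n_species=12, abundance=250,
    interaction="accumulator", interaction_target="sp001",
    d_int=10.0, strength=1.0, seed=42,
)
community = generate_community(scenario)
ensemble = run_null_ensemble(
    community, "sp001", model="heterogeneous", n_sim=199,
    seed=1, grid=RadiusGrid.regular(50.0), mode="large_small",
)
results = [gof_rank_test(ensemble, iv) for iv in default_intervals()]
cls = classify_species("sp001", results, "heterogeneous")
for iv, label in cls.labels.items():
    res = cls.results[iv]
    print(f"{iv.label:>7}  u0={res.u0:8.3f}  rank={res.rank:3d}  {label}")
```

Output:

```
  1-10m  u0=  10.445  rank=200  accumulator
 11-20m  u0=   1.823  rank=200  accumulator
 21-30m  u0=   0.011  rank=132  no_effect
 31-40m  u0=   0.000  rank=  1  no_effect
 41-50m  u0=   0.000  rank=  1  no_effect
```

The planted interaction is recovered exactly where it was placed: the
observed accumulated deviation `u0` ranks 200th of 200 (far beyond the
critical rank 190) on the 1–10 m interval, the signal bleeds into 11–20 m
because ISAR is cumulative, and the large-distance intervals — where local
richness is saturated — are correctly labeled no-effect.

For shell-driven runs the same pipeline is available as a CLI:

```
isar simulate --scenario scenario.yaml --out census.csv
isar run --config run.yaml --seed 1 --out results/
isar sweep --config run.yaml --bandwidths 30,50,70
```

`isar run` writes `classification.csv`, `summary.csv`, `envelopes.csv` and
a `manifest.json` (seed, config hash, versions) from which any table can be
regenerated.

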