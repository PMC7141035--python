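# phyloldg

Latitudinal gradients of species richness and assemblage phylogenetic
structure, for reserve-level survey data — with a variable-importance stage
for separating contemporary from historical climate drivers, and a synthetic
data generator implementing phylogenetic niche conservatism (PNC).

## The scientific problem

Insect richness across a continental reserve network need not follow the
"classical" latitudinal diversity gradient: when faunas of different
biogeographic affinities (Oriental, Palearctic, widespread) overlap at
midlatitudes, total richness can be hump-shaped. The PNC hypothesis predicts
that historical winter coldness — the coldest-month temperature at the Last
Glacial Maximum (LGM_MTCM) — filters lineages by their ancestral thermal
tolerances, leaving two signatures:

1. **Richness**: groups of tropical origin thin out northward, temperate
   groups southward, and their overlap produces an interior richness peak.
2. **Phylogenetic structure**: assemblages at higher latitude are composed
   of evolutionarily more derived orders.

The second signature is measured by **mean root distance**,

```
MRD = (1/S) * sum_i RD(order_i)
```

where `RD` is the node-count depth of a species' order in a rooted
order-level phylogeny (branch lengths ignored) and the sum runs over the `S`
species recorded in a reserve. Richness and MRD are regressed on latitude
(linear and quadratic OLS; a concave quadratic `y = a*lat^2 + b*lat + c`
peaks at `-b/(2a)`), screened against each predictor one at a time
(`100 * R^2` with significance codes), and modeled jointly: backward AIC
elimination, variance-inflation pruning (`VIF = 1/(1 - R2_j)`, threshold 10),
a 200-tree bootstrap regression forest with out-of-bag permutation
importance normalized to the maximum, and Moran's I of the forest residuals
over equal-count great-circle distance classes with permutation p-values.

## Worked example

```python
import phyloldg as pl

dataset = pl.simulate_dataset(pl.SimConfig(seed=7))   # 110 reserves, PNC filter
summary = pl.reserve_summaries(dataset)

quad = pl.fit_latitudinal(summary["richness_total"], summary["lat"],
                          "quadratic", log_y=True)
print(pl.peak_latitude(quad))
for col in ("mrd", "mrd_warm", "mrd_cold"):
    print(col, pl.fit_latitudinal(summary[col], summary["lat"], "linear").b)
```

prints (run it: `python examples/03_latitudinal_gradients.py`):

```
total richness is hump-shaped (a = -0.0020 < 0, R2 = 0.66); peak at 30.48 deg N [ok]
MRD slope vs latitude, all species : +0.0165 per deg (p = 2.2e-26)
MRD slope vs latitude, warm clades : +0.0147 per deg (p = 5.5e-31)
MRD slope vs latitude, cold clades : +0.0092 per deg (p = 6.9e-24)
```

Total richness peaks at ~30.5° N — the latitude band where the simulated
Oriental and Palearctic faunas overlap — and MRD rises with latitude:
northern assemblages are dominated by more derived orders, exactly the PNC
signature the generator encodes. `examples/04_variable_importance.py` shows
the multivariate stage recovering the generative driver with normalized
importance `LGM_MTCM = 1.00`.

Each capability has a short narrative script under `examples/`; a thin CLI
(`phyloldg simulate | mrd | gradients | importance | full-run`) orchestrates
the same stages on files.

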