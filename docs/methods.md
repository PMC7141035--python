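# Methods

## Mean root distance

The unit of analysis is a reserve's species list with order-level taxonomy.
Root distance (RD) of an order is the number of internal nodes on the path
from the tree root to that order's tip, counting the root ("root-inclusive",
the default): every tip of a star tree has RD 1, and a caterpillar tree
`(((A,B),C),D);` gives A,B = 3, C = 2, D = 1. An alternative "edge-count"
convention (root excluded, values lower by exactly 1) is exposed because the
literature is not unanimous; since the two differ by a constant for every
tip, MRD *differences* between assemblages and all latitudinal MRD *slopes*
are convention-invariant, which the test suite asserts by grafting a new
root above random trees.

MRD weights species, not orders: a reserve with 40 beetle species and one
dragonfly is dominated by the beetles' RD. Species whose order is absent
from the tree are excluded with a warning and an explicit count rather than
imputed; an assemblage with no scorable species is an error. Polytomies are
kept as single nodes — random resolution would inflate node counts
nondeterministically. A species assigned to different orders in different
input rows is a hard error, never silently deduplicated.

Orders are classed by geohistorical origin: origination ages inside
274–320 Ma (Late Carboniferous–Early Permian) are "cold" clades, ages inside
145–250 Ma (Triassic–Jurassic) are "warm" clades, anything else is
unclassified. The default table carries the six species-rich orders:
Hemiptera (310 Ma) and Coleoptera (282 Ma) cold; Hymenoptera (250 Ma),
Orthoptera (215 Ma), Diptera (170 Ma), Lepidoptera (156 Ma) warm.

## Environmental covariates

Rasters are exchanged as ESRI ASCII grids (text, no-data sentinel honored
from the header); reserve values are arithmetic means over valid cells —
reserve masks are precomputed inputs, not polygon clips. Derivations:

* **TR** (topographic roughness) = `1/cos(slope·π/180)`, slope in
  `[0, 90)` degrees, so flat cells give exactly 1. π is used at machine
  precision; a truncated 5-digit value would change TR by < 1e-6 relative.
* **Slope** from a DEM via Horn's 3×3 finite-difference kernel (the standard
  GIS algorithm), borders by edge replication; no-data holes are filled from
  neighboring valid cells before differencing and masked out afterwards.
* **Climate indices** from 12 monthly layers: MAP = annual *sum* of monthly
  precipitation (the WorldClim convention, not the mean of months), MTCM =
  minimum monthly mean temperature, MAT = mean. The same operations apply to
  LGM layers; **T_Anomaly** = MAT(current) − MAT(LGM), positive = warming
  since the glacial maximum.
* **NDVI**: per cell, the monthly value is the maximum over that month's
  ~10-day composites (cloud suppression), the annual value the mean of 12
  monthly values, and the reserve scalar the mean over valid cells and
  years. The result is invariant to dekad order within a month.
* **PET** is accepted as a supplied per-reserve value. A Thornthwaite
  monthly helper (`thornthwaite_pet`) is provided for convenience when no
  PET grid exists, but it is not the canonical source and nothing in the
  pipeline depends on it. PET² is stored alongside PET to allow humped
  energy–richness responses in linear models.
* AREA units (ha vs km²) only shift the intercept of models using
  ln(AREA), so the table accepts whatever unit the survey uses.

## Gradient fits

OLS throughout. Richness responses are modeled as natural logs (the
species–area relation is a power law and richness distributions are
right-skewed); zero counts — a group absent from a reserve — are dropped
from that group's log fit with a logged count, mirroring presence-only
species lists. MRD responses are modeled raw. The model p-value is the
F-test of the whole model; per-coefficient p-values are reported but do not
drive significance codes (ns, ', *, **, *** at 0.1/0.05/0.01/0.001). A peak
latitude is reported only from a *concave* quadratic whose vertex −b/(2a)
falls inside the observed latitude span; otherwise the reason (upward
parabola, degenerate, exterior vertex) is returned instead of a number.
Peaks estimated on the log scale are the vertex of the log response; the
monotone transform preserves the argmax of the fitted curve.

The bivariate table is the single-predictor screen: for every predictor ×
response pair, 100·R² with a significance code, the top three predictors per
response flagged. Cells with fewer than three complete cases are marked
unavailable rather than extrapolated.

## Importance stage

1. **Backward AIC** on the OLS of the (transformed) response: at each step
   the single removal that most lowers AIC is applied; ties are broken by
   predictor declaration order; the stage stops when no removal lowers AIC.
2. **VIF pruning**: iteratively remove the predictor with the largest
   VIF = 1/(1 − R²_j) until all VIF ≤ 10. Numerically perfect collinearity
   is reported as infinite. The AIC→VIF order is the default (and matches
   the order the two screens are usually described in); the reverse order is
   available as a switch.
3. **Random forest**: `n_trees` (default 200) regression trees, each on a
   bootstrap resample, `max_features = p/3` (the regression-forest
   convention). Importance is *out-of-bag permutation* importance — for each
   tree, each retained predictor is permuted over the tree's OOB rows and
   the OOB-MSE increase recorded — averaged over trees, floored at 0, and
   divided by the maximum so the top predictor scores exactly 1. OOB
   permutation importance was chosen over node-impurity importance because
   it is scale-robust and nonnegative after flooring, which the
   normalize-to-max convention requires. The forest is built by explicit
   seeded bootstrap over `sklearn` decision trees (scikit-learn's forest
   class does not expose OOB permutation importance), making runs bitwise
   reproducible for a fixed seed and input order.
4. **Moran's I of OOB residuals**: pairwise great-circle distances between
   reserve centroids (WGS84 decimal degrees, haversine, R = 6371 km) are
   binned into distance classes with approximately equal pair counts
   (default 10, quantile edges); within class k, with binary weights,
   `I_k = (n/ΣW)·(Σ w_ij z_i z_j)/(Σ z_i²)` for centered residuals z.
   Two-sided p-values come from seeded random permutations of the residuals
   over locations (default 999), comparing |I − E[I]| with E[I] = −1/(n−1).
   The report sets a "residuals spatially independent" flag when no class
   has p < 0.05; with 10 classes this familywise criterion rejects ~40% of
   the time even under perfect independence, so the per-class p-values are
   always reported alongside the flag and readers should interpret the flag
   conservatively.

A predictor identical to the response triggers a leakage warning (its
importance is trivially 1). Reports record the seed, every drop with its
reason (AIC vs VIF), and every Moran class, so a Table-style matrix with
blanks can always be reconstructed from the JSON.

## Synthetic data generator

There is no generative model in the underlying study; the generator encodes
the *mechanisms* its discussion asserts in the simplest consistent forms,
and records every equation in the dataset's truth record, so tests never
rely on unstated structure.

* **Network**: 110 reserves, latitude uniform on 19.1–51.5° N, longitude
  uniform on 82–130° E (longitude only exercises the great-circle code; no
  east–west structure is generated).
* **Climate**: MTCM = 46 − 1.4·lat + N(0, 4) °C (≈ +19 °C south, −26 °C
  north; sample corr(MTCM, lat) ≈ −0.95). LGM winter coldness is the same
  gradient shifted by a latitude-dependent glacial cooling (4 + 0.1·lat °C)
  with *independent* noise N(0, 6): glacial-era local climate is not a
  deterministic function of today's, and the independent component is what
  lets a multivariate analysis distinguish the historical from the
  contemporary covariate at all (with shared noise the two are statistically
  interchangeable and no method could attribute the signal). Remaining
  covariates (MAP, LGM_MAP, PET, NDVI, MAT, T_Anomaly) follow declared
  linear gradients with their own noise; AREA, GDP, POP are lognormal;
  E_max, NCT, TR are gradient-free fillers.
* **Species pool**: 350 Oriental, 350 Palearctic, 300 widespread species,
  assigned to seven orders with realistic richness weights on a fixed
  order-level topology whose root distances run 1 (Odonata) to 6
  (Diptera/Lepidoptera). Thermal-tolerance intervals per affinity:
  Oriental cold limits N(−5, 5) (cold-intolerant), warm limits N(30, 3);
  Palearctic cold N(−35, 8), warm N(−8, 5) — the low warm limit is a proxy
  for competitive exclusion from the warm south, not a physiological claim;
  widespread cold N(−25, 8), warm N(12, 6). Cold limits are then lowered by
  `3 °C × (RD − mean RD)` (derived orders more cold-tolerant), keeping the
  shift comparable to the within-affinity spread so the filter reshapes
  order composition along the whole gradient rather than only in a tail.
  These effect sizes are not derivable from any survey; they were chosen
  once to make the encoded patterns detectable at n = 110 and are recorded
  as arbitrary.
* **Occupancy**: species i occurs at reserve r iff
  `cold_limit_i ≤ LGM_MTCM_r ≤ warm_limit_i` — deterministic given the
  draws. Switches select contemporary-climate filtering (contrast
  experiments), a climate-independent Bernoulli(0.5) null, or a degenerate
  everyone-everywhere pool.

What passing tests show — and what they do not: the generator produces
presence/absence from a single sharp environmental filter with no dispersal
limitation, no sampling error, no spatial autocorrelation beyond what the
latitude gradients induce, and no species interactions beyond the warm-limit
proxy. Recovery of the driver at importance 1.0 therefore demonstrates the
pipeline's correctness under its own assumptions, not that any real survey's
richness is driven by LGM winter coldness.

## Numerical choices and degenerate inputs

Ties everywhere break by declaration order; a single seed governs bootstrap
and permutation draws; constant responses yield p = 1 rather than NaN;
constant predictors are rejected by name; zero-variance VIF columns, empty
Moran classes, all-no-data grids, and all-unscorable assemblages raise
informative errors. `1/cos(60°·π/180)` is 2 only to ~1e-15 in double
arithmetic — closed-form identities are asserted to 1e-12, not bit-exactly.

## Problem sizes

Default analysis sizes (110 reserves, 1,000-species pool, 200 trees, 999
permutations) run the full pipeline in seconds; replicate-based checks in
the test suite use 10–20 seeds, which keeps the whole suite under a minute
while giving binomial bounds with comfortable margins.

## Known limitations

* MRD is computed at order resolution; within-order heterogeneity is
  invisible, and the basal-most order's RD depends on the root convention
  (slopes do not).
* OOB permutation importance shares signal between correlated survivors of
  the VIF screen; importances are rankings, not effect sizes.
* The quadratic peak is a parametric vertex; it says nothing about
  asymmetry or plateau width.
* Biogeographic affinity labels are taken as given; the package never infers
  them.
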