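# Methods

## The model in one paragraph

A species' suitable habitat at time *t* is the set of 50-km grid points
whose climate vector falls inside the species' climate envelope at *t*.
Both pieces are time-dependent: the climate grid at *t* is an affine blend
of two end-member climatologies weighted by the benthic δ18O curve, and the
envelope at *t* is obtained by evolving the occurrence-fitted modern
envelope backwards along the phylogeny under Brownian motion. Habitat time
series built this way over the last 320 ky yield displacement statistics
(how far and how fast the habitat center moved per °C of mean-annual-
temperature change), which are then extrapolated to warm-future scenarios.

## Isotope-scaled interpolation

The blend weight at an isotope sample of age *t* is
`w(t) = (δ(t) − δ_modern) / (δ_glacial − δ_modern)`; every grid cell and
every variable is interpolated independently as `(1−w)·modern + w·LGM`.
Assumptions and choices:

- δ18O is treated as a *global scalar* proxy: no geographic variation in
  the temperature signal, no sub-curve interpolation between isotope
  samples (slices exist exactly where the curve has samples).
- Anchors default to the samples nearest 0 and 21 kya (the Last Glacial
  Maximum); both are configurable on load.
- Extrapolation (`w < 0`, e.g. the last interglacial, or `w > 1`, deeper
  glacials) is allowed without limit; a log warning fires beyond
  `|w − 0.5| > 1.5` because blends degrade the further they extrapolate
  from the end members.
- Precipitation (mm units in the registry) is clamped at 0 after blending;
  temperature is never clamped. At the anchors no clamping can trigger, so
  `w ∈ {0, 1}` reproduces the end members bit-for-bit.
- Ratio variables (BIO3, BIO7) are blended independently like all others;
  a consistency recomputation (BIO7 = BIO5 − BIO6, BIO3 = 100·BIO2/BIO7)
  was considered and rejected as the default because independent blending
  is the simplest faithful construction; the synthetic generator keeps its
  end members internally consistent either way.
- The warm-future grid uses `w = −ΔT / (mean modern BIO1 − mean LGM BIO1)`
  over shared non-missing cells — a single continental scale, not a
  per-cell one — so the future mean annual temperature exceeds the modern
  mean by exactly ΔT before clamping. The two scenario presets are +1.1 °C
  and +6.4 °C by 2100, annualized over 90 years.

## Envelopes

- **BIOCLIM (rectilinear)**: per-variable order statistics of the training
  climates, percentile pairs (0, 100) and (5, 95). Percentiles use linear
  interpolation between closest ranks; bounds are inclusive. Membership is
  invariant to per-variable monotone affine rescaling applied consistently
  to training and query data.
- **Mahalanobis ellipsoid**: mean vector plus sample covariance (ddof 1);
  suitability probability is the upper-tail chi-square (df = number of
  variables) of the squared Mahalanobis distance, thresholded at
  p > {0.1 … 0.5}. A singular covariance (n ≤ dim, or constant training
  data) gets `1e−8 × mean diagonal` (or `1e−8` if the diagonal is zero)
  added to the diagonal.
- Points with any missing variable are classified unsuitable rather than
  erroring: a cell cannot satisfy bounds it has no values for (this is how
  ice-covered LGM cells drop out).
- All 19 registry variables enter every envelope by default; subsetting is
  a registry option, not a default.

Model selection fits all seven variants per species, projects each back
onto the modern grid, and credits a variant when the modeled distribution
is statistically indistinguishable from the known one (Welch p > 0.05,
configurable); ranking is by that count, ties broken by mean overlap
`OP = 2|A∩B| / (|A|+|B|)`. Stability is probed by refitting on 25%
subsamples 100 times (seeded).

The distribution t-test deserves a note: the field construction compares
*geographic centers* using the point dispersions as standard deviations and
point counts as sample sizes. This is not a textbook two-sample test on raw
data; we implement it as a Welch test on the between-center great-circle
distance with Welch–Satterthwaite degrees of freedom, the closest standard
reading. Identical centers give t = 0, p = 1 by definition.

## Ancestral envelopes

Each bound (variable × {min, max}) is an independent Brownian trait. The
most-likely internal-node values are computed by solving the weighted-
Laplacian system in which every internal node is the 1/branch-length
weighted average of its neighbours with tips fixed; this coincides with the
GLS estimates built from the full BM covariance matrix (shared root-to-MRCA
path lengths), which is kept as the independent oracle in the tests.
Uncertainty in node states and in divergence times is out of scope — point
estimates only, matching the workflow this package supports.

Along a branch the trait is linearly interpolated between the branch's end
values; times deeper than a tip's parent walk up successive ancestors, and
times beyond the root raise. Because min and max evolve independently, a
reconstructed lower bound can cross its upper bound; both are then
collapsed to their midpoint and a warning logged. Trees are in My, pipeline
times in kya (1 My = 1000 kya), converted centrally.

## Evolutionary mode: D = r·t^a

Pairwise absolute tip divergences are modeled as |N(0, σ(t)²)| with
σ(t) = r·t^a·√(π/2), which makes E|D| = r·t^a exact. For each candidate
`a` the rate has the closed form `r(a) = sqrt(mean((D/t^a)²)) / √(π/2)`;
`a` is maximized on a 0.01 grid over [0, 1] with bounded golden-section
refinement, so the fit is deterministic. Two caveats are intrinsic to the
pairwise construction and documented rather than "fixed": pairs are treated
as independent although they share tree paths, and single-realization
estimates of `a` scatter widely (on 20-tip Brownian simulations individual
fits range roughly 0–1 while the mean across replicates sits near 0.5).
Permutation p-values shuffle trait values across tips — tree geometry and
pair times fixed — refit, and use the add-one estimator
`(1 + #{estimate ≥ observed}) / (n_perm + 1)`, one-tailed per parameter.
Mode labels use configurable bands (stabilizing below 0.25, diversifying
above 0.75, random between); the raw exponent is always reported alongside,
since no pure threshold rule is canonical.

## Pipeline statistics

- Habitat time series come in three variants: `climate_only` (modern
  envelope, moving climate), `phylogeny_only` (evolving envelope, modern
  climate), `both`. One distribution per lineage per isotope slice.
- Displacement records are **all pairs** of time slices (C(101, 2) = 5,050
  at the default 101 slices): per-lineage center displacement (great-circle
  km; R = 6371 km sphere) and signed extent change (2,500 km² per 50-km
  point), averaged over lineages, against the difference in continental
  mean annual temperature. A lineage empty at *any* slice is dropped from
  the averages entirely — the conservative treatment of intermittently
  undetectable habitat; a per-pair exclusion variant sits behind a flag.
- Rates regress |Δcenter| (or |Δextent|) on |ΔMAT| by OLS, with
  case-resampling bootstrap SE (degenerate resamples redrawn) and a
  randomization p from shuffling ΔMAT across records; fully seeded.
- The fossil check asks, per fossil, whether at some slice inside its age
  range its latitude is at or south of the northernmost modeled suitable
  point within ±5° longitude (fossils can only *refute* models by lying
  north of all suitable habitat); no suitable band points at any in-range
  slice → inconclusive; an age range wholly outside the modeled span is an
  error.
- Future projections reuse the modern tip envelopes (a 90-year horizon of
  along-branch evolution is negligible).

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* the analysis assumes, not any real
geography: a rectangular lattice (default 40 × 50 = 2,000 points over a
55° × 45° domain, ≈50-km rows), modern BIO1 falling with latitude plus
smooth correlated noise, precipitation positive and increasing with
temperature, derived variables internally consistent, and an LGM whose
latitude-weighted cooling averages exactly `glacial_cooling_c` (default
7 °C, inside the 6–8 °C glacial–interglacial contrast). The isotope curve
is a hand-shaped sawtooth (slow build-ups, fast terminations, ~100-ky
period, one glacial slightly heavier than the 21-kya anchor so some slices
extrapolate with w > 1) plus small noise; 101 samples over 0–320 kya so the
all-pairs count matches 5,050. Trees are pure-birth, rescaled to 10 My
depth, with terminal branches extended by a common draw so the final
speciation does not produce zero-length edges. Envelope bounds evolve by BM
at `0.12 × continental SD per √My` — narrow (35th–65th percentile) root
bounds on BIO1/BIO12, wide bounds elsewhere — chosen so that species
occupy latitude bands that actually migrate under the glacial cooling while
envelope evolution stays an order of magnitude slower, the regime the
decomposition statistics are designed to resolve. Occurrences are the
suitable points of each species' true envelope thinned by 10% occupancy
noise; fossils are drawn from modeled past habitat with ≤15-ky age jitter.

Consequences for interpretation: passing tests show the machinery is
correct and internally consistent — exact interpolation of affine truths,
oracle-equivalent reconstructions, recoverable rates. They do not show that
real climates interpolate affinely, that real niches evolve by BM, or that
real range maps are occupancy-thinned boxes; on real data the same
quantities would carry those additional model errors. A species whose
evolved envelope matches no modern grid cell has no occurrences; the
workflow then prunes the tree to the species with modern ranges.

## Numerical details

- Percentiles: numpy linear interpolation; covariance: ddof = 1.
- GLS solve: dense `numpy.linalg.solve` on the internal-node system (trees
  here are small); tolerance against the covariance oracle 1e−8.
- Exponent grid step 0.01, golden refinement `xatol = 1e−6`, refinement
  never allowed to fall below the best grid value.
- Great-circle distances: haversine, R = 6371.0 km, clamped into [0, 1]
  before `arcsin`.
- CSV round-trips: values written as `%.17g`, read with pandas
  `float_precision="round_trip"`, so finite grids round-trip bit-exactly.
- Default problem sizes (2,000 points, 101 slices, 8 species, 1,000
  bootstrap/randomization replicates) run the full pipeline in well under a
  minute on one CPU; they are the package's standard study conditions, and
  tests reuse smaller instances of the same generators.

## Known limitations

- No dispersal limitation, biotic interactions or occupancy dynamics: the
  envelope defines *suitable*, not *occupied*, habitat.
- Geographic centers average raw degrees; domains spanning the antimeridian
  are unsupported (synthetic domains avoid ±180°).
- The δ18O proxy has no spatial structure; regional climate histories that
  decouple from the global curve are invisible to the interpolation.
- Within-branch evolution is strictly linear between reconstructed nodes;
  no stochastic anagenesis within glacial cycles.
- The ellipsoid envelope's probability is a chi-square tail on Mahalanobis
  distance — one standard construction among several; model-selection
  results involving it should be read qualitatively.
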