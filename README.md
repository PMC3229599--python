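# paleophylo

Paleophylogeographic modeling of species' suitable habitat through
glacial–interglacial cycles.

Species shift their geographic ranges as climate swings between glacial and
interglacial states. Estimating *how fast* they have done so in the past
gives a baseline against which modern, anthropogenic displacement rates can
be judged. `paleophylo` implements that workflow for ectotherm-style clades
(the motivating system is North American rattlesnakes): it couples

1. **isotope-scaled paleoclimate interpolation** — any time slice is an
   affine blend of two end-member climate grids (modern and Last Glacial
   Maximum), weighted by the benthic δ18O curve:
   `w(t) = (δ(t) − δ_modern) / (δ_glacial − δ_modern)`, so `w = 0`
   reproduces the modern grid and `w = 1` the LGM grid;
2. **climate envelopes** — rectilinear BIOCLIM boxes (min/max or 5th/95th
   percentile bounds over the 19 bioclimatic variables BIO1–BIO19) and
   Mahalanobis-ellipsoid probability envelopes, exposed as scikit-learn
   style estimators (`fit` on occurrence climates, `predict` suitability);
3. **phylogenetically evolving envelopes** — each envelope bound is a trait
   evolving by Brownian motion on a time-calibrated tree; most-likely node
   values are the GLS/BM ancestral estimates, and the envelope anywhere
   along a branch is the linear interpolation between the branch's ends;
4. **evolutionary-mode estimation** — maximum-likelihood fit of
   `D = r·t^a` to pairwise tip divergences (`a ≈ 0` stabilizing selection,
   `a ≈ 0.5` Brownian motion, `a ≈ 1` diversifying selection) with
   permutation p-values;
5. **displacement statistics** — per-lineage habitat time series over
   320 ky, all-pairs changes in geographic center (km) and areal extent
   (km²) regressed on the concurrent change in mean annual temperature,
   with bootstrap SE and randomization tests; a fossil northern-edge
   consistency check; and projections onto +1.1 °C and +6.4 °C warm-future
   scenarios annualized over a 90-year horizon.

Real gridded climatologies and occurrence databases are deliberately out of
scope; a first-class synthetic-data module generates end-member grids,
isotope curves, trees, ranges and fossils with the statistical structure
the analysis assumes, so the entire pipeline is testable offline.

## Worked example

```python
from paleophylo import SyntheticScenario, full_analysis

res = full_analysis(SyntheticScenario(seed=1), n_boot=200, n_rand=200)
```

prints (via the summary snippet in `scripts/acceptance.py` or your own):

```text
pairwise records:        5050
center slope:            133.44 km/degC (bootstrap SE 1.14)
R^2 (center ~ |dMAT|):   0.760
background rate:         0.0089 km/yr
climate vs phylogeny:    449.8 km vs 19.4 km per slice pair
fossils consistent:      41/41
future +1.1 degC:         299.1 km over 90 yr (3.32 km/yr)
future +6.4 degC:         1289.2 km over 90 yr (14.32 km/yr)
```

Reading this: 101 isotope-dated time slices give C(101, 2) = 5,050 slice
pairs; on this synthetic continent the habitat center moves ~133 km per °C
of mean-annual-temperature change, temperature explains ~76% of the
variance in displacement, and the long-term background displacement rate is
~0.009 km/yr — two to three orders of magnitude below the rates implied by
the two warm-future scenarios. Climate change moves habitat roughly 23×
more than envelope evolution does over the same intervals, and all 41
fossils drawn from the modeled past habitat pass the northern-edge check.

A CLI mirrors the stages: `paleophylo simulate | interpolate | future |
fit | evo-mode | project` (see `--help`).

## Layout

- `src/paleophylo/` — library (`grid`, `isotopes`, `interpolate`,
  `envelopes`, `phylogeny`, `ancestral`, `evomode`, `habitat_stats`,
  `pipeline`, `synthetic`, `workflow`, `cli`)
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details, limitations
- `tests/` — unit, property and acceptance tests
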