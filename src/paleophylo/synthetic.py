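"""Synthetic inputs with the statistical structure the analysis assumes.

Real analyses of this kind consume gridded modern and Last Glacial Maximum
climates, a composite benthic δ18O curve, a time-calibrated phylogeny with
occurrence-based climate envelopes at the tips, and dated fossils.  This
module generates stand-ins for all of them from a single seed:

* a sawtooth glacial-cycle isotope curve (slow ice build-up, fast
  terminations, ~100-ky period) sampled 101 times over 0–320 kya;
* two spatially correlated end-member climate grids on a fixed lattice with
  a latitudinal temperature gradient, temperature-correlated precipitation,
  internally consistent derived variables (BIO7 = BIO5 − BIO6,
  BIO3 = 100·BIO2/BIO7), and a continental-mean glacial cooling matching the
  6–8 °C glacial–interglacial contrast;
* an ultrametric birth–death tree whose tip envelope bounds evolved from a
  root envelope by Brownian motion (true node values retained for recovery
  tests);
* species occurrences obtained by thresholding the modern climate with each
  tip's true envelope, thinned by independent occupancy noise;
* fossils drawn from past modeled habitats, with age ranges jittered around
  the source slice (so every generated fossil is consistent by
  construction).

Everything is reproducible from the scenario seed alone.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .envelopes import BioclimEnvelope, project_envelope
from .grid import ClimateGrid, HabitatDistribution
from .isotopes import IsotopeSeries
from .phylogeny import Phylogeny
from .variables import DEFAULT_REGISTRY

# Shape of one glacial cycle, as a normalized "ice volume" polygon over age
# (kya): interglacials near 0, glacial maxima near 1, rapid terminations.
_CYCLE_CONTROL = [
    (0.0, 0.05), (8.0, 0.12), (14.0, 0.85), (19.0, 0.98), (21.0, 1.00),
    (26.0, 0.95), (35.0, 0.80), (60.0, 0.50), (85.0, 0.30), (95.0, 0.35),
    (110.0, 0.60), (122.0, 0.90), (128.0, 1.02), (133.0, 1.06), (140.0, 0.25),
    (150.0, 0.15), (170.0, 0.40), (190.0, 0.55), (215.0, 0.80), (235.0, 1.00),
    (241.0, 0.95), (247.0, 0.18), (255.0, 0.12), (270.0, 0.40), (295.0, 0.70),
    (312.0, 0.95), (320.0, 1.00),
]

_DELTA_LIGHT = 3.2   # per mil, interglacial benthic d18O
_DELTA_RANGE = 1.8   # glacial-interglacial amplitude


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for a full synthetic analysis."""

    seed: int = 0
    n_points: int = 2000
    n_slices: int = 101
    n_species: int = 8
    tree_depth_my: float = 10.0
    bm_rate_scale: float = 0.12      # per-trait BM sd per sqrt(My), x continental SD
    glacial_cooling_c: float = 7.0   # continental mean LGM cooling (6-8 range)
    occupancy_noise: float = 0.1     # P(drop) per suitable occurrence point
    max_age_kya: float = 320.0
    ice_band: bool = False           # LGM-missing high-latitude band

    def __post_init__(self):
        if min(self.n_points, self.n_slices, self.n_species) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.occupancy_noise <= 1.0:
            raise ValueError("occupancy_noise must lie in [0, 1]")


@dataclass
class SyntheticBundle:
    scenario: SyntheticScenario
    isotopes: IsotopeSeries
    modern: ClimateGrid
    lgm: ClimateGrid
    tree: Phylogeny
    tip_envelopes: dict = field(repr=False)       # species -> true BioclimEnvelope
    true_node_values: dict = field(repr=False)    # (code, side) -> (n_nodes,) array
    occurrences: dict = field(repr=False)         # species -> sorted point ids


def _seeds(scenario: SyntheticScenario, n: int):
    return np.random.SeedSequence(scenario.seed).spawn(n)


def make_isotope_curve(scenario: SyntheticScenario,
                       rng: np.random.Generator | None = None) -> IsotopeSeries:
    """Sawtooth glacial-cycle δ18O curve over 0–320 kya with small noise."""
    if scenario.n_slices < 3:
        raise ValueError("need at least 3 slices")
    if rng is None:
        rng = np.random.default_rng(_seeds(scenario, 5)[0])
    ages = np.linspace(0.0, scenario.max_age_kya, scenario.n_slices)
    ctrl_a, ctrl_g = (np.array(c) for c in zip(*_CYCLE_CONTROL))
    g = np.interp(ages, ctrl_a * (scenario.max_age_kya / 320.0), ctrl_g)
    delta = _DELTA_LIGHT + _DELTA_RANGE * g + rng.normal(0.0, 0.01, len(ages))
    return IsotopeSeries.from_samples(ages, delta)


def _smooth_field(rng, shape, sigma=3.0):
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_end_members(scenario: SyntheticScenario,
                     rng: np.random.Generator | None = None
                     ) -> tuple[ClimateGrid, ClimateGrid]:
    """Modern and LGM end-member grids on a shared lattice.

    Modern mean annual temperature falls with latitude plus smooth spatial
    noise; the LGM subtracts a latitude-weighted cooling whose continental
    mean equals ``glacial_cooling_c``; precipitation is regenerated from the
    cooled temperatures through the same temperature–precipitation relation,
    so it is positive and positively associated with temperature.
    """
    if scenario.n_points < 100:
        raise ValueError("need at least 100 grid points")
    if rng is None:
        rng = np.random.default_rng(_seeds(scenario, 5)[1])
    lon0, lon1, lat0, lat1 = -125.0, -70.0, 15.0, 60.0
    n_lat = max(2, int(round(np.sqrt(scenario.n_points * (lat1 - lat0) / (lon1 - lon0)))))
    n_lon = max(2, scenario.n_points // n_lat)
    lats = np.linspace(lat0, lat1, n_lat)
    lons = np.linspace(lon0, lon1, n_lon)
    LON, LAT = np.meshgrid(lons, lats)          # (n_lat, n_lon)
    latf = (LAT - lat0) / (lat1 - lat0)

    f1, f2, f3, f4 = (_smooth_field(rng, (n_lat, n_lon)) for _ in range(4))

    def assemble(bio1, amp, label):
        bio2 = np.clip(11.0 + 1.2 * f3, 2.0, None)
        bio5 = bio1 + amp + 0.5 * bio2
        bio6 = bio1 - amp - 0.5 * bio2
        bio7 = bio5 - bio6
        bio3 = 100.0 * bio2 / bio7
        bio4 = 70.0 * amp + 20.0 * f4
        precip = np.clip(40.0 + 42.0 * bio1 + 70.0 * f4, 0.0, None)
        cols = {
            "BIO1": bio1, "BIO2": bio2, "BIO3": bio3, "BIO4": bio4,
            "BIO5": bio5, "BIO6": bio6, "BIO7": bio7,
            "BIO8": bio1 + 3.0 + 0.3 * f4, "BIO9": bio1 - 3.0 + 0.3 * f1,
            "BIO10": bio1 + 0.8 * amp, "BIO11": bio1 - 0.8 * amp,
            "BIO12": precip, "BIO13": 0.16 * precip, "BIO14": 0.03 * precip,
            "BIO15": np.clip(38.0 + 6.0 * f2, 5.0, None),
            "BIO16": 0.42 * precip, "BIO17": 0.09 * precip,
            "BIO18": 0.30 * precip, "BIO19": 0.20 * precip,
        }
        values = np.column_stack([cols[c].ravel() for c in DEFAULT_REGISTRY.codes])
        n = values.shape[0]
        return ClimateGrid(np.arange(n), LON.ravel(), LAT.ravel(), values,
                           DEFAULT_REGISTRY, label=label)

    amp_mod = 12.0 + 11.0 * latf + 1.0 * f2
    modern = assemble(28.0 - 26.0 * latf + 1.5 * f1, amp_mod, "modern")

    cooling = scenario.glacial_cooling_c * (0.55 + 0.9 * latf)
    lgm = assemble(28.0 - 26.0 * latf + 1.5 * f1 - cooling,
                   amp_mod + 0.12 * cooling, "LGM")
    if scenario.ice_band:
        ice = lgm.lat > lat0 + 0.93 * (lat1 - lat0)
        lgm.values[ice, :] = np.nan
    return modern, lgm


def make_tree_and_envelopes(scenario: SyntheticScenario, modern: ClimateGrid,
                            rng: np.random.Generator | None = None
                            ) -> tuple[Phylogeny, dict, dict]:
    """Ultrametric tree plus envelope bounds evolved by Brownian motion.

    The root envelope brackets the mid-range of the continental climates:
    narrow (35th–65th percentile) on annual temperature and precipitation —
    the variables that actually delimit ranges — and wide on the rest.  Each
    bound then evolves independently along the tree; a node where a lower
    bound would cross its upper bound is redrawn.
    """
    if scenario.n_species < 2:
        raise ValueError("need at least 2 species")
    if rng is None:
        rng = np.random.default_rng(_seeds(scenario, 5)[2])
    from dendropy.model import birthdeath

    py_rng = random.Random(int(rng.integers(0, 2**31 - 1)))
    tree_d = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0,
        num_extant_tips=scenario.n_species, rng=py_rng)
    # the simulator stops at the final speciation event, so the youngest tip
    # branches have zero length; extend every terminal branch by one common
    # draw (keeps the tree ultrametric and all branch lengths positive)
    extension = py_rng.expovariate(2.0) + 0.05
    tree_d.seed_node.edge.length = None   # drop the meaningless stem edge
    for k, leaf in enumerate(tree_d.leaf_node_iter()):
        leaf.taxon.label = f"sp{k + 1:02d}"
        leaf.edge.length += extension
    height = max(leaf.distance_from_root() for leaf in tree_d.leaf_node_iter())
    for edge in tree_d.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scenario.tree_depth_my / height
    tree = Phylogeny(tree_d)

    codes = DEFAULT_REGISTRY.codes
    focal = {"BIO1", "BIO12"}
    complete = modern.values[modern.complete_mask()]
    root_lo, root_hi, rates = {}, {}, {}
    for j, code in enumerate(codes):
        col = complete[:, j]
        sd = float(np.std(col))
        rates[code] = scenario.bm_rate_scale * max(sd, 1e-12)
        if code in focal:
            root_lo[code] = float(np.percentile(col, 35))
            root_hi[code] = float(np.percentile(col, 65))
        else:
            span = float(np.ptp(col))
            root_lo[code] = float(np.percentile(col, 1)) - 0.1 * span
            root_hi[code] = float(np.percentile(col, 99)) + 0.1 * span

    n_nodes = tree.n_nodes
    node_vals = {(c, s): np.empty(n_nodes) for c in codes for s in ("min", "max")}
    for c in codes:
        node_vals[(c, "min")][0] = root_lo[c]
        node_vals[(c, "max")][0] = root_hi[c]
    for node in range(1, n_nodes):  # preorder: parent already assigned
        parent = tree.parent[node]
        ell = tree.branch_length[node]
        for c in codes:
            sd = rates[c] * np.sqrt(max(ell, 0.0))
            p_lo = node_vals[(c, "min")][parent]
            p_hi = node_vals[(c, "max")][parent]
            for _ in range(200):
                lo = p_lo + rng.normal(0.0, sd)
                hi = p_hi + rng.normal(0.0, sd)
                if lo < hi:
                    break
            else:
                mid = 0.5 * (p_lo + p_hi)
                lo, hi = mid - 1e-6, mid + 1e-6
            node_vals[(c, "min")][node] = lo
            node_vals[(c, "max")][node] = hi

    tip_envelopes = {}
    for name in tree.tip_names:
        i = tree.tip_id(name)
        lower = np.array([node_vals[(c, "min")][i] for c in codes])
        upper = np.array([node_vals[(c, "max")][i] for c in codes])
        tip_envelopes[name] = BioclimEnvelope.from_bounds(lower, upper, 5.0, 95.0)
    return tree, tip_envelopes, node_vals


def make_ranges(modern: ClimateGrid, tip_envelopes: dict,
                occupancy_noise: float = 0.1,
                rng: np.random.Generator | None = None) -> dict:
    """Occurrences per species: suitable points thinned by occupancy noise."""
    if rng is None:
        rng = np.random.default_rng(0)
    out = {}
    for species, env in tip_envelopes.items():
        dist = project_envelope(env, modern, species)
        ids = np.array(sorted(dist.member_ids), dtype=int)
        if len(ids) == 0:
            out[species] = ids  # flagged empty but kept
            continue
        keep = rng.random(len(ids)) >= occupancy_noise
        out[species] = ids[keep]
    return out


def occurrences_frame(occurrences: dict, grid: ClimateGrid) -> pd.DataFrame:
    rows = []
    for species, ids in occurrences.items():
        if len(ids) == 0:
            continue
        idx = grid.index_of_ids(ids)
        rows.append(pd.DataFrame({"species": species, "point_id": ids,
                                  "lon": grid.lon[idx], "lat": grid.lat[idx]}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["species", "point_id", "lon", "lat"])


def make_fossils(ages_kya, genus_series: list[HabitatDistribution],
                 grid: ClimateGrid, n_fossils: int = 41, seed=None,
                 age_jitter_ky: float = 15.0) -> pd.DataFrame:
    """Fossils sampled from past modeled habitats, ages jittered into ranges.

    Each fossil's age range contains the slice it was drawn from, so the
    fossil-consistency check must judge every generated fossil consistent.
    """
    rng = np.random.default_rng(seed)
    ages_kya = np.asarray(ages_kya, dtype=float)
    valid = [s for s, d in enumerate(genus_series) if not d.is_empty]
    if not valid:
        raise ValueError("no non-empty habitat slices to sample fossils from")
    rows = []
    for _ in range(n_fossils):
        s = valid[rng.integers(0, len(valid))]
        dist = genus_series[s]
        lon, lat = dist.coords(grid)
        k = rng.integers(0, len(lon))
        age = float(ages_kya[s])
        rows.append({
            "lon": float(lon[k]), "lat": float(lat[k]),
            "min_age_kya": max(0.0, age - rng.uniform(0.0, age_jitter_ky)),
            "max_age_kya": min(float(ages_kya.max()),
                               age + rng.uniform(0.0, age_jitter_ky)),
        })
    return pd.DataFrame(rows)


def generate(scenario: SyntheticScenario) -> SyntheticBundle:
    """All pipeline inputs, fully determined by the scenario seed."""
    s_curve, s_grid, s_tree, s_ranges, _ = _seeds(scenario, 5)
    isotopes = make_isotope_curve(scenario, np.random.default_rng(s_curve))
    modern, lgm = make_end_members(scenario, np.random.default_rng(s_grid))
    tree, tip_envelopes, node_vals = make_tree_and_envelopes(
        scenario, modern, np.random.default_rng(s_tree))
    occurrences = make_ranges(modern, tip_envelopes, scenario.occupancy_noise,
                              np.random.default_rng(s_ranges))
    return SyntheticBundle(scenario, isotopes, modern, lgm, tree,
                           tip_envelopes, node_vals, occurrences)


# --------------------------------------------------------- trait simulators

def simulate_bm_tips(tree: Phylogeny, root: float = 0.0, rate: float = 1.0,
                     rng=None) -> dict:
    """Brownian-motion tip values (variance = rate² · branch length)."""
    rng = np.random.default_rng(rng)
    vals = np.empty(tree.n_nodes)
    vals[0] = root
    for node in range(1, tree.n_nodes):
        ell = tree.branch_length[node]
        vals[node] = vals[tree.parent[node]] + rng.normal(0.0, rate * np.sqrt(ell))
    return {name: float(vals[tree.tip_id(name)]) for name in tree.tip_names}


def simulate_ou_tips(tree: Phylogeny, theta: float, sigma: float = 1.0,
                     optimum: float = 0.0, root: float = 0.0, rng=None) -> dict:
    """Ornstein–Uhlenbeck tip values; strong theta yields saturating divergence."""
    rng = np.random.default_rng(rng)
    vals = np.empty(tree.n_nodes)
    vals[0] = root
    for node in range(1, tree.n_nodes):
        ell = tree.branch_length[node]
        decay = np.exp(-theta * ell)
        var = sigma**2 * (1.0 - np.exp(-2.0 * theta * ell)) / (2.0 * theta)
        mean = optimum + (vals[tree.parent[node]] - optimum) * decay
        vals[node] = mean + rng.normal(0.0, np.sqrt(var))
    return {name: float(vals[tree.tip_id(name)]) for name in tree.tip_names}
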