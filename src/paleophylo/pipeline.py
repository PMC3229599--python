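"""Paleophylogeographic pipeline stages.

A *paleophylogeographic model* is a time series of suitable-habitat maps:
for every sample of the isotope curve, the lineage's climate envelope —
evolved along its branch to that time — is projected onto the isotope-scaled
paleoclimate grid for the same time.  Three variants isolate the drivers:
``climate_only`` holds the envelope at its modern (tip) state and lets the
climate change, ``phylogeny_only`` holds the climate modern and lets the
envelope evolve, and ``both`` combines the two.

Downstream statistics: all-pairs displacement records between time slices
(center shift in km, signed areal-extent change in km², concurrent change in
mean annual temperature), OLS rate regressions with bootstrap SE and a
randomization p, the fossil northern-edge consistency check, and the
future-scenario projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ancestral import EnvelopeReconstruction
from .envelopes import project_envelope
from .geo import haversine_km
from .grid import ClimateGrid, HabitatDistribution
from .habitat_stats import DEFAULT_CELL_AREA_KM2
from .interpolate import future_climate, interpolate_climate, weight_from_isotope
from .isotopes import IsotopeSeries

logger = logging.getLogger(__name__)

MODES = ("climate_only", "phylogeny_only", "both")


@dataclass
class HabitatTimeSeries:
    """Per-lineage habitat distributions at every isotope slice."""

    ages_kya: np.ndarray
    weights: np.ndarray
    lineages: tuple[str, ...]
    distributions: dict = field(repr=False)   # lineage -> list[HabitatDistribution]
    mean_temp_c: np.ndarray                   # mean annual temperature per slice
    grid: ClimateGrid = field(repr=False)     # coordinate reference (point set)
    mode: str = "both"

    @property
    def n_slices(self) -> int:
        return len(self.ages_kya)

    def genus_union(self) -> list[HabitatDistribution]:
        """Per-slice union of all lineages' suitable points."""
        out = []
        for s, age in enumerate(self.ages_kya):
            members = frozenset().union(
                *(self.distributions[lin][s].member_ids for lin in self.lineages))
            out.append(HabitatDistribution("genus", float(age), members,
                                           self.grid.label))
        return out


def build_timeseries(recon: EnvelopeReconstruction, modern: ClimateGrid,
                     lgm: ClimateGrid, isotopes: IsotopeSeries,
                     lineages=None, mode: str = "both",
                     max_age_kya: float = 320.0,
                     temp_code: str = "BIO1") -> HabitatTimeSeries:
    """Habitat distribution per (lineage, isotope slice) up to ``max_age_kya``."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    lineages = tuple(lineages) if lineages is not None else tuple(recon.tree.tip_names)
    unknown = [l for l in lineages if l not in recon.tree.tip_names]
    if unknown:
        raise ValueError(f"no reconstruction for lineage(s): {unknown}")
    keep = isotopes.ages_kya <= max_age_kya
    ages = isotopes.ages_kya[keep]
    weights = np.array([weight_from_isotope(isotopes, a).w for a in ages])

    dists: dict = {lin: [] for lin in lineages}
    mean_temp = np.empty(len(ages))
    for s, (age, w) in enumerate(zip(ages, weights)):
        if mode == "phylogeny_only":
            grid_t = modern
        else:
            grid_t = interpolate_climate(modern, lgm, w, label=f"t={age:g}kya")
        mean_temp[s] = grid_t.mean_of(temp_code)
        for lin in lineages:
            env_time = 0.0 if mode == "climate_only" else float(age)
            env = recon.envelope_at(lin, env_time)
            dists[lin].append(project_envelope(env, grid_t, lin, time_kya=float(age)))
    return HabitatTimeSeries(ages, weights, lineages, dists, mean_temp,
                             modern, mode)


def pairwise_displacements(series: HabitatTimeSeries, exclude=(),
                           cell_area_km2: float = DEFAULT_CELL_AREA_KM2,
                           per_slice_exclusion: bool = False) -> pd.DataFrame:
    """All C(T, 2) slice-pair displacement records, averaged over lineages.

    By default a lineage with intermittently undetectable habitat (empty at
    any slice) is dropped from the averages entirely — the conservative
    treatment; ``per_slice_exclusion=True`` instead drops a lineage only
    from the pairs where one endpoint is empty.
    """
    T = series.n_slices
    if T < 2:
        raise ValueError("need at least two time slices")
    lineages = [l for l in series.lineages if l not in set(exclude)]
    if len(lineages) == 0:
        raise ValueError("all lineages excluded; no displacement records")
    n_pts = np.array([[series.distributions[l][s].n_points for s in range(T)]
                      for l in lineages], dtype=float)      # (L, T)
    nonempty = n_pts > 0
    if not per_slice_exclusion:
        always = np.all(nonempty, axis=1)
        dropped = [l for l, ok in zip(lineages, always) if not ok]
        if dropped:
            logger.info("excluding lineage(s) with intermittently empty habitat: %s",
                        dropped)
        lineages = [l for l, ok in zip(lineages, always) if ok]
        n_pts = n_pts[always]
        nonempty = nonempty[always]
    if len(lineages) == 0:
        raise ValueError("all lineages excluded; no displacement records")

    cen_lon = np.full((len(lineages), T), np.nan)
    cen_lat = np.full((len(lineages), T), np.nan)
    for li, lin in enumerate(lineages):
        for s in range(T):
            d = series.distributions[lin][s]
            if d.n_points:
                lon, lat = d.coords(series.grid)
                cen_lon[li, s] = lon.mean()
                cen_lat[li, s] = lat.mean()

    iu, ju = np.triu_indices(T, k=1)
    d_center = np.full((len(lineages), len(iu)), np.nan)
    for li in range(len(lineages)):
        ok = nonempty[li, iu] & nonempty[li, ju]
        if np.any(ok):
            d_center[li, ok] = haversine_km(
                cen_lon[li, iu[ok]], cen_lat[li, iu[ok]],
                cen_lon[li, ju[ok]], cen_lat[li, ju[ok]])
    d_extent = (n_pts[:, ju] - n_pts[:, iu]) * cell_area_km2
    d_extent[~(nonempty[:, iu] & nonempty[:, ju])] = np.nan

    with np.errstate(invalid="ignore"):
        mean_center = np.nanmean(d_center, axis=0)
        mean_extent = np.nanmean(d_extent, axis=0)
    n_used = np.sum(~np.isnan(d_center), axis=0)
    return pd.DataFrame({
        "age_i_kya": series.ages_kya[iu],
        "age_j_kya": series.ages_kya[ju],
        "delta_t_ky": series.ages_kya[ju] - series.ages_kya[iu],
        "delta_center_km": mean_center,
        "delta_extent_km2": mean_extent,
        "delta_mat_c": series.mean_temp_c[ju] - series.mean_temp_c[iu],
        "n_lineages": n_used,
        "mode": series.mode,
    })


def background_rate_km_per_yr(records: pd.DataFrame) -> float:
    """Mean displacement rate over all slice pairs (km per year)."""
    r = records.dropna(subset=["delta_center_km"])
    return float(np.mean(r["delta_center_km"] / (r["delta_t_ky"] * 1000.0)))


@dataclass(frozen=True)
class RateRegression:
    slope: float          # km/°C or km²/°C
    intercept: float
    r_squared: float
    bootstrap_se: float
    randomization_p: float
    n: int
    response: str


def regress_on_temperature(records: pd.DataFrame, response: str = "center",
                           n_boot: int = 1000, n_rand: int = 1000,
                           seed=None) -> RateRegression:
    """OLS of |Δresponse| on |ΔMAT| with bootstrap SE and randomization p.

    Displacement is unsigned; extent change enters as its absolute value.
    The bootstrap resamples records (cases); the randomization shuffles the
    temperature changes across records and compares |slope|.
    """
    col = {"center": "delta_center_km", "extent": "delta_extent_km2"}[response]
    df = records.dropna(subset=[col, "delta_mat_c"])
    x = np.abs(df["delta_mat_c"].to_numpy(dtype=float))
    y = np.abs(df[col].to_numpy(dtype=float))
    if len(x) < 3:
        raise ValueError("need at least 3 records for a regression")
    if np.ptp(x) == 0:
        raise ValueError("no variance in temperature change")
    fit = sps.linregress(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while np.ptp(x[idx]) == 0:  # degenerate resample: redraw
            idx = rng.integers(0, n, size=n)
        boot[b] = sps.linregress(x[idx], y[idx]).slope
    ge = 0
    for _ in range(n_rand):
        perm = rng.permutation(x)
        ge += abs(sps.linregress(perm, y).slope) >= abs(fit.slope)
    return RateRegression(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), bootstrap_se=float(np.std(boot, ddof=1)),
        randomization_p=float((1 + ge) / (n_rand + 1)), n=n, response=response)


def fossil_consistency(fossils: pd.DataFrame, ages_kya: np.ndarray,
                       genus_series: list[HabitatDistribution],
                       grid: ClimateGrid, lon_band_deg: float = 5.0
                       ) -> pd.DataFrame:
    """Northern-edge check of each fossil against the modeled genus habitat.

    A fossil is *consistent* when, at some slice within its age range, its
    latitude does not exceed the northernmost suitable point within
    ±``lon_band_deg`` of its longitude; *inconsistent* when every in-range
    slice has suitable points in the band all south of it; *inconclusive*
    when the band is empty at every in-range slice.
    """
    ages_kya = np.asarray(ages_kya, dtype=float)
    rows = []
    for k, f in fossils.reset_index(drop=True).iterrows():
        lo, hi = float(f["min_age_kya"]), float(f["max_age_kya"])
        if lo > hi:
            raise ValueError("fossil min_age_kya must be <= max_age_kya")
        if hi < ages_kya.min() or lo > ages_kya.max():
            raise ValueError(
                f"fossil age range [{lo}, {hi}] kya lies outside the "
                f"modeled span [{ages_kya.min():g}, {ages_kya.max():g}] kya")
        in_range = np.flatnonzero((ages_kya >= lo) & (ages_kya <= hi))
        if len(in_range) == 0:  # overlapping but between samples: nearest slice
            in_range = np.array([int(np.argmin(np.abs(ages_kya - 0.5 * (lo + hi))))])
        verdict = "inconclusive"
        best_edge = np.nan
        for s in in_range:
            dist = genus_series[s]
            if dist.is_empty:
                continue
            lon, lat = dist.coords(grid)
            band = np.abs(lon - float(f["lon"])) <= lon_band_deg
            if not np.any(band):
                continue
            edge = float(lat[band].max())
            if np.isnan(best_edge) or edge > best_edge:
                best_edge = edge
            if float(f["lat"]) <= edge:
                verdict = "consistent"
                break
            verdict = "inconsistent"
        rows.append({"fossil": k, "lon": float(f["lon"]), "lat": float(f["lat"]),
                     "min_age_kya": lo, "max_age_kya": hi,
                     "northern_edge_lat": best_edge, "verdict": verdict})
    return pd.DataFrame(rows)


def future_projection(recon: EnvelopeReconstruction, modern: ClimateGrid,
                      lgm: ClimateGrid, delta_T: float, horizon_yr: float = 90.0,
                      cell_area_km2: float = DEFAULT_CELL_AREA_KM2,
                      lineages=None) -> pd.DataFrame:
    """Per-lineage habitat displacement under a warm-future scenario.

    Modern (tip) envelopes are projected on the modern grid and on the
    future grid for a ``delta_T`` °C warming; a century of along-branch
    evolution is negligible, so envelopes are not time-scaled.  The rate is
    the center displacement divided by the horizon (default 90 years).
    """
    if delta_T < 0:
        raise ValueError("delta_T must be >= 0")
    lineages = tuple(lineages) if lineages is not None else tuple(recon.tree.tip_names)
    fut = (future_climate(modern, lgm, delta_T) if delta_T > 0 else modern)
    rows = []
    for lin in lineages:
        env = recon.envelope_at(lin, 0.0)
        d_now = project_envelope(env, modern, lin)
        d_fut = project_envelope(env, fut, lin)
        if d_now.is_empty or d_fut.is_empty:
            disp = np.nan
        else:
            lon0, lat0 = d_now.coords(modern)
            lon1, lat1 = d_fut.coords(modern)
            disp = haversine_km(lon0.mean(), lat0.mean(), lon1.mean(), lat1.mean())
        rows.append({
            "lineage": lin, "delta_T_c": delta_T,
            "displacement_km": disp,
            "delta_extent_km2": (d_fut.n_points - d_now.n_points) * cell_area_km2,
            "rate_km_per_yr": disp / horizon_yr,
        })
    return pd.DataFrame(rows)


def annualize_displacement(displacement_km: float, horizon_yr: float = 90.0) -> float:
    """Displacement over a horizon expressed as km per year."""
    if horizon_yr <= 0:
        raise ValueError("horizon must be positive")
    return displacement_km / horizon_yr
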