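"""Descriptors and fit tests for habitat distributions, and model selection.

Three descriptors summarise a distribution of 50-km points: the geographic
center (mean longitude/latitude), the sample standard deviation of
great-circle distances of members from that center, and the point count
(converted to areal extent at 2,500 km² per point by default).  A modeled
distribution is compared to the known one with a Welch two-sample t-test on
the between-center distance, using the dispersions as standard deviations
and the point counts as sample sizes; robustness is probed by refitting on
25% subsamples, and agreement by the Sørensen-type overlap index
OP = 2|A∩B| / (|A| + |B|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .envelopes import (ELLIPSOID_THRESHOLDS, BioclimEnvelope,
                        MahalanobisEnvelope, project_envelope)
from .geo import haversine_km
from .grid import ClimateGrid, HabitatDistribution

#: Area represented by one 50-km grid point.
DEFAULT_CELL_AREA_KM2 = 2500.0


@dataclass(frozen=True)
class DistributionStats:
    center_lon: float
    center_lat: float
    dispersion_km: float      # NaN when n_points < 2
    n_points: int
    areal_extent_km2: float

    @property
    def is_empty(self) -> bool:
        return self.n_points == 0


def distribution_stats(dist: HabitatDistribution, grid: ClimateGrid,
                       cell_area_km2: float = DEFAULT_CELL_AREA_KM2
                       ) -> DistributionStats:
    """Center, dispersion and extent of a habitat distribution.

    An empty distribution yields NaN center/dispersion and zero extent
    rather than an error.
    """
    n = dist.n_points
    if n == 0:
        return DistributionStats(np.nan, np.nan, np.nan, 0, 0.0)
    lon, lat = dist.coords(grid)
    c_lon, c_lat = float(np.mean(lon)), float(np.mean(lat))
    if n >= 2:
        d = haversine_km(lon, lat, c_lon, c_lat)
        disp = float(np.std(d, ddof=1))
    else:
        disp = np.nan
    return DistributionStats(c_lon, c_lat, disp, n, n * cell_area_km2)


def t_test_distributions(a: DistributionStats, b: DistributionStats
                         ) -> tuple[float, float]:
    """Welch t-test of the distance between two distribution centers.

    The between-center great-circle distance is the effect, the dispersions
    serve as standard deviations and the point counts as sample sizes
    (Welch–Satterthwaite degrees of freedom).  Identical centers give
    t = 0, p = 1.
    """
    if a.is_empty or b.is_empty:
        raise ValueError("cannot compare empty distributions")
    if a.n_points < 2 or b.n_points < 2:
        raise ValueError("both distributions need n >= 2 for a t-test")
    d = haversine_km(a.center_lon, a.center_lat, b.center_lon, b.center_lat)
    if d == 0.0:
        return 0.0, 1.0
    va = a.dispersion_km**2 / a.n_points
    vb = b.dispersion_km**2 / b.n_points
    se = np.sqrt(va + vb)
    if se == 0.0:
        return np.inf, 0.0
    t = d / se
    df = (va + vb) ** 2 / (va**2 / (a.n_points - 1) + vb**2 / (b.n_points - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def overlap_index(a: HabitatDistribution, b: HabitatDistribution) -> float:
    """Sørensen-type overlap 2|A∩B| / (|A|+|B|); 0 when both sets are empty."""
    total = a.n_points + b.n_points
    if total == 0:
        return 0.0
    return 2.0 * len(a.member_ids & b.member_ids) / total


def _fit_variant(method: str, X: np.ndarray):
    """One of the seven envelope variants by tag."""
    if method == "bioclim100":
        return BioclimEnvelope(0.0, 100.0).fit(X)
    if method == "bioclim95":
        return BioclimEnvelope(5.0, 95.0).fit(X)
    if method.startswith("ellipsoid"):
        thr = float(method.split("_", 1)[1])
        return MahalanobisEnvelope(p_threshold=thr).fit(X)
    raise ValueError(f"unknown envelope variant: {method}")


ALL_VARIANTS = ("bioclim100", "bioclim95") + tuple(
    f"ellipsoid_{t}" for t in ELLIPSOID_THRESHOLDS)


def _occurrence_climates(occ_ids, grid: ClimateGrid) -> np.ndarray:
    idx = grid.index_of_ids(occ_ids)
    X = grid.values[idx]
    keep = ~np.any(np.isnan(X), axis=1)
    return X[keep]


def subsample_stability(occ_ids, grid: ClimateGrid, method: str = "bioclim95",
                        fraction: float = 0.25, reps: int = 100, seed=None,
                        cell_area_km2: float = DEFAULT_CELL_AREA_KM2
                        ) -> pd.DataFrame:
    """Refit the envelope on random subsamples and re-test against the known set.

    Each replicate draws ``fraction`` of the occurrences without replacement,
    refits the chosen variant, projects it on the grid and compares the
    modeled distribution to the full known one (Welch p and overlap OP).
    """
    occ_ids = sorted(int(i) for i in occ_ids)
    n = len(occ_ids)
    k = int(round(fraction * n))
    if k < 1:
        raise ValueError("fraction * n must be >= 1")
    if n < 4:
        raise ValueError("need at least 4 known occurrences")
    known = HabitatDistribution("known", 0.0, frozenset(occ_ids), grid.label)
    known_stats = distribution_stats(known, grid, cell_area_km2)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        sub = rng.choice(occ_ids, size=k, replace=False)
        X = _occurrence_climates(sub, grid)
        env = _fit_variant(method, X)
        model = project_envelope(env, grid, "model")
        st = distribution_stats(model, grid, cell_area_km2)
        if st.n_points >= 2:
            t, p = t_test_distributions(st, known_stats)
        else:
            t, p = np.nan, np.nan
        rows.append({"rep": rep, "n_model": st.n_points, "t": t, "p": p,
                     "overlap": overlap_index(model, known)})
    return pd.DataFrame(rows)


def select_best_model(occurrences: dict, grid: ClimateGrid,
                      variants=ALL_VARIANTS, alpha: float = 0.05,
                      cell_area_km2: float = DEFAULT_CELL_AREA_KM2
                      ) -> pd.DataFrame:
    """Rank envelope variants by how many species they reproduce.

    For each variant and species the envelope is fitted on the species'
    occurrence climates and projected back onto the grid; the variant is
    credited when the modeled distribution is statistically
    indistinguishable from the known one (Welch p > alpha).  Ranking is by
    that count, ties broken by mean overlap.
    """
    if not occurrences:
        raise ValueError("need at least one species")
    rows = []
    for variant in variants:
        hits, overlaps, pvals = 0, [], []
        for species, occ_ids in occurrences.items():
            occ_ids = sorted(int(i) for i in occ_ids)
            known = HabitatDistribution(species, 0.0, frozenset(occ_ids), grid.label)
            X = _occurrence_climates(occ_ids, grid)
            env = _fit_variant(variant, X)
            model = project_envelope(env, grid, species)
            st_m = distribution_stats(model, grid, cell_area_km2)
            st_k = distribution_stats(known, grid, cell_area_km2)
            if st_m.n_points >= 2 and st_k.n_points >= 2:
                _, p = t_test_distributions(st_m, st_k)
            else:
                p = 0.0
            pvals.append(p)
            hits += p > alpha
            overlaps.append(overlap_index(model, known))
        rows.append({"variant": variant, "n_indistinguishable": hits,
                     "mean_p": float(np.mean(pvals)),
                     "mean_overlap": float(np.mean(overlaps))})
    out = pd.DataFrame(rows).sort_values(
        ["n_indistinguishable", "mean_overlap"], ascending=False,
        kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
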