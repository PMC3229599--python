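"""Climate grids and habitat distributions.

A :class:`ClimateGrid` is a fixed set of geographic points (≈50-km spaced in
typical use) with a values matrix, one column per registry variable, at a
single time slice.  Missing climate (e.g. ice-covered cells at glacial
maxima) is encoded as NaN; a point missing any variable is excluded from
suitability classification.  A :class:`HabitatDistribution` is the subset of
grid points classified suitable for one lineage at one time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .variables import DEFAULT_REGISTRY, VariableRegistry


@dataclass
class ClimateGrid:
    point_ids: np.ndarray          # (n,) int, unique
    lon: np.ndarray                # (n,) degrees east
    lat: np.ndarray                # (n,) degrees north
    values: np.ndarray             # (n, n_vars) float, NaN = missing
    registry: VariableRegistry = field(default_factory=lambda: DEFAULT_REGISTRY)
    label: str = ""

    def __post_init__(self) -> None:
        self.point_ids = np.asarray(self.point_ids, dtype=int)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.point_ids)
        if len(np.unique(self.point_ids)) != n:
            raise ValueError("grid point ids must be unique")
        if self.lon.shape != (n,) or self.lat.shape != (n,):
            raise ValueError("lon/lat must be 1-D with one entry per point")
        if not (np.all(np.isfinite(self.lon)) and np.all(np.isfinite(self.lat))):
            raise ValueError("coordinates must be finite")
        if np.any(self.lon < -180) or np.any(self.lon > 180):
            raise ValueError("longitude outside [-180, 180]")
        if np.any(self.lat < -90) or np.any(self.lat > 90):
            raise ValueError("latitude outside [-90, 90]")
        if self.values.shape != (n, len(self.registry)):
            raise ValueError(
                f"values must be (n_points, n_variables) = ({n}, {len(self.registry)}), "
                f"got {self.values.shape}"
            )

    @property
    def n_points(self) -> int:
        return len(self.point_ids)

    def column(self, code: str) -> np.ndarray:
        """Values of one variable across all points (NaN where missing)."""
        return self.values[:, self.registry.index(code)]

    def mean_of(self, code: str) -> float:
        """Mean over non-missing points of one variable."""
        col = self.column(code)
        if np.all(np.isnan(col)):
            raise ValueError(f"variable {code} is missing everywhere")
        return float(np.nanmean(col))

    def complete_mask(self) -> np.ndarray:
        """True where the point has no missing variable."""
        return ~np.any(np.isnan(self.values), axis=1)

    def index_of_ids(self, ids: Iterable[int]) -> np.ndarray:
        """Row indices of the given point ids (error on unknown id)."""
        order = {int(p): i for i, p in enumerate(self.point_ids)}
        try:
            return np.array([order[int(i)] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"point id {exc.args[0]} not in grid") from None

    def same_points(self, other: "ClimateGrid", tol: float = 1e-9) -> bool:
        return (
            self.n_points == other.n_points
            and np.array_equal(self.point_ids, other.point_ids)
            and np.allclose(self.lon, other.lon, atol=tol)
            and np.allclose(self.lat, other.lat, atol=tol)
        )


@dataclass(frozen=True)
class HabitatDistribution:
    """Suitable grid points for one species/lineage at one time."""

    name: str
    time_kya: float
    member_ids: frozenset
    grid_ref: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_ids", frozenset(int(i) for i in self.member_ids))
        if self.time_kya < 0:
            raise ValueError("time_kya must be >= 0")

    @property
    def n_points(self) -> int:
        return len(self.member_ids)

    @property
    def is_empty(self) -> bool:
        return len(self.member_ids) == 0

    def coords(self, grid: ClimateGrid) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of the member points, in stable id order."""
        ids = sorted(self.member_ids)
        idx = grid.index_of_ids(ids)
        return grid.lon[idx], grid.lat[idx]
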