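"""Readers and writers for the package's plain-text interchange formats.

All tables are comma-separated UTF-8 with a header row and "." decimals:

* climate grid (long form): ``point_id,lon,lat,variable,value`` — empty
  value marks missing climate;
* occurrences: ``species,point_id,lon,lat``;
* fossils: ``lon,lat,min_age_kya,max_age_kya``;
* isotope curve: ``age_kya,delta18O``;
* trees: Newick with branch lengths (see :mod:`paleophylo.phylogeny`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import ClimateGrid
from .isotopes import IsotopeSeries
from .variables import DEFAULT_REGISTRY, VariableRegistry


def read_climate_table(path, registry: VariableRegistry | None = None,
                       label: str = "") -> ClimateGrid:
    """Read a long-form climate CSV into a :class:`ClimateGrid`.

    Raises on duplicate (point, variable) pairs and on variable codes absent
    from the registry.
    """
    registry = registry or DEFAULT_REGISTRY
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"point_id", "lon", "lat", "variable", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"climate table needs columns {sorted(required)}")
    unknown = set(df["variable"].unique()) - set(registry.codes)
    if unknown:
        raise ValueError(f"unknown variable code(s): {sorted(unknown)}")
    if df.duplicated(subset=["point_id", "variable"]).any():
        dup = df[df.duplicated(subset=["point_id", "variable"])].iloc[0]
        raise ValueError(
            f"duplicate (point, variable) pair: ({dup['point_id']}, {dup['variable']})")

    pts = df.drop_duplicates("point_id")[["point_id", "lon", "lat"]]
    bad = df.groupby("point_id")[["lon", "lat"]].nunique()
    if (bad > 1).any().any():
        raise ValueError("a point_id appears with inconsistent coordinates")
    pts = pts.sort_values("point_id").reset_index(drop=True)
    wide = df.pivot(index="point_id", columns="variable", values="value")
    wide = wide.reindex(index=pts["point_id"], columns=list(registry.codes))
    return ClimateGrid(
        point_ids=pts["point_id"].to_numpy(),
        lon=pts["lon"].to_numpy(),
        lat=pts["lat"].to_numpy(),
        values=wide.to_numpy(dtype=float),
        registry=registry,
        label=label,
    )


def write_climate_table(grid: ClimateGrid, path) -> None:
    """Write a grid as long CSV; missing cells get an empty value field."""
    n, k = grid.values.shape
    df = pd.DataFrame({
        "point_id": np.repeat(grid.point_ids, k),
        "lon": np.repeat(grid.lon, k),
        "lat": np.repeat(grid.lat, k),
        "variable": list(grid.registry.codes) * n,
        "value": grid.values.ravel(),
    })
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_occurrences(path) -> pd.DataFrame:
    """Occurrence table with at least species + (point_id or lon/lat)."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("occurrence table needs a 'species' column")
    if "point_id" not in df.columns and not {"lon", "lat"}.issubset(df.columns):
        raise ValueError("occurrence table needs point_id or lon/lat columns")
    return df


def write_occurrences(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_fossils(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"lon", "lat", "min_age_kya", "max_age_kya"}
    if not required.issubset(df.columns):
        raise ValueError(f"fossil table needs columns {sorted(required)}")
    if (df["min_age_kya"] > df["max_age_kya"]).any():
        raise ValueError("fossil min_age_kya must be <= max_age_kya")
    return df


def write_fossils(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_isotope_curve(path, modern_anchor_age: float | None = None,
                       glacial_anchor_age: float | None = None) -> IsotopeSeries:
    df = pd.read_csv(path)
    if not {"age_kya", "delta18O"}.issubset(df.columns):
        raise ValueError("isotope curve needs columns age_kya, delta18O")
    df = df.sort_values("age_kya")
    return IsotopeSeries.from_samples(
        df["age_kya"].to_numpy(), df["delta18O"].to_numpy(),
        modern_anchor_age=modern_anchor_age, glacial_anchor_age=glacial_anchor_age)


def write_isotope_curve(series: IsotopeSeries, path) -> None:
    pd.DataFrame({"age_kya": series.ages_kya, "delta18O": series.delta18o}
                 ).to_csv(path, index=False)
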