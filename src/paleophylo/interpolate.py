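"""Isotope-scaled paleoclimate interpolation.

Any time slice is modeled as a proportional (affine) blend of two end-member
climates — the modern interglacial and the Last Glacial Maximum — with the
blend weight read off the benthic δ18O curve:

    w(t) = (δ(t) − δ_modern) / (δ_glacial − δ_modern)

so w = 0 reproduces the modern grid exactly and w = 1 the LGM grid.  Weights
outside [0, 1] extrapolate (e.g. the last interglacial was lighter than
modern); extrapolation is permitted but increasingly uncertain far from the
end members, and a warning is logged for |w − 0.5| > 1.5.  Precipitation
(mm) is clamped at 0 after blending; temperature is never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import ClimateGrid
from .isotopes import IsotopeSeries

logger = logging.getLogger(__name__)

#: |w - 0.5| beyond which extrapolation is flagged in the log.
EXTRAPOLATION_WARN = 1.5


@dataclass(frozen=True)
class InterpolationWeight:
    """Dimensionless blend weight (0 = modern, 1 = glacial end member)."""

    w: float
    time_kya: float


def weight_from_isotope(series: IsotopeSeries, age_kya: float) -> InterpolationWeight:
    """Blend weight at one isotope sample's age.

    The age must be an actual sample of the curve — the curve is not
    interpolated between its own samples.
    """
    d_t = series.delta_at(age_kya)
    d_mod = series.delta_at(series.modern_anchor_age)
    d_gla = series.delta_at(series.glacial_anchor_age)
    if d_gla == d_mod:
        raise ValueError("degenerate anchors: modern and glacial delta18O are equal")
    w = (d_t - d_mod) / (d_gla - d_mod)
    return InterpolationWeight(w=float(w), time_kya=float(age_kya))


def interpolate_climate(modern: ClimateGrid, lgm: ClimateGrid,
                        w: InterpolationWeight | float,
                        label: str | None = None) -> ClimateGrid:
    """Affine blend (1−w)·modern + w·LGM of two aligned grids.

    Cells missing (NaN) in either end member are missing in the result.
    Precipitation columns are clamped at ≥ 0 mm after blending.
    """
    if isinstance(w, InterpolationWeight):
        time_kya, wv = w.time_kya, w.w
    else:
        time_kya, wv = None, float(w)
    if not modern.same_points(lgm):
        raise ValueError("modern and LGM grids must share the same point set")
    if modern.registry.codes != lgm.registry.codes:
        raise ValueError("modern and LGM grids must share one variable registry")
    if abs(wv - 0.5) > EXTRAPOLATION_WARN:
        logger.warning("interpolation weight w=%.3f extrapolates far beyond the "
                       "end members; expect reduced accuracy", wv)
    values = (1.0 - wv) * modern.values + wv * lgm.values
    precip = np.asarray(modern.registry.precipitation_mask(), dtype=bool)
    values[:, precip] = np.clip(values[:, precip], 0.0, None)
    if label is None:
        label = f"t={time_kya:g}kya" if time_kya is not None else f"w={wv:g}"
    return ClimateGrid(modern.point_ids.copy(), modern.lon.copy(), modern.lat.copy(),
                       values, modern.registry, label=label)


def future_climate(modern: ClimateGrid, lgm: ClimateGrid, delta_T: float,
                   temp_code: str = "BIO1") -> ClimateGrid:
    """Warm-future grid for a prescribed mean-annual-temperature increase.

    The δ18O proxy maps one unit of blend weight onto the continental mean
    temperature contrast of the two end members, so a warming of ``delta_T``
    °C corresponds to w = −delta_T / (mean modern − mean LGM); the resulting
    grid's mean annual temperature exceeds the modern mean by exactly
    ``delta_T`` (before precipitation clamping).
    """
    if delta_T < 0:
        raise ValueError("delta_T must be >= 0")
    both = ~np.isnan(modern.column(temp_code)) & ~np.isnan(lgm.column(temp_code))
    if not np.any(both):
        raise ValueError(f"no shared non-missing {temp_code} cells")
    m_mean = float(np.mean(modern.column(temp_code)[both]))
    l_mean = float(np.mean(lgm.column(temp_code)[both]))
    if m_mean == l_mean:
        raise ValueError("end members have equal mean temperature; "
                         "cannot scale the future weight")
    w = -delta_T / (m_mean - l_mean)
    return interpolate_climate(modern, lgm, w, label=f"future+{delta_T:g}C")
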