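"""Registry of bioclimatic variables.

The 19 standard bioclimatic variables (BIO1–BIO19) summarise monthly
temperature and precipitation as annual means, extremes, seasonality and
quarter aggregates.  Every climate grid and envelope in one analysis shares a
single registry so that value matrices are column-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True)
class Variable:
    """One climate variable: short code, human description, units."""

    code: str
    description: str
    units: str  # "°C" | "mm" | "index"


#: The 19 standard bioclimatic variables.
BIOCLIM_19: tuple[Variable, ...] = (
    Variable("BIO1", "Annual Mean Temperature", "°C"),
    Variable("BIO2", "Mean Diurnal Range", "°C"),
    Variable("BIO3", "Isothermality (100 * BIO2 / BIO7)", "index"),
    Variable("BIO4", "Temperature Seasonality (100 * SD)", "index"),
    Variable("BIO5", "Max Temperature of Warmest Month", "°C"),
    Variable("BIO6", "Min Temperature of Coldest Month", "°C"),
    Variable("BIO7", "Temperature Annual Range (BIO5 - BIO6)", "°C"),
    Variable("BIO8", "Mean Temperature of Wettest Quarter", "°C"),
    Variable("BIO9", "Mean Temperature of Driest Quarter", "°C"),
    Variable("BIO10", "Mean Temperature of Warmest Quarter", "°C"),
    Variable("BIO11", "Mean Temperature of Coldest Quarter", "°C"),
    Variable("BIO12", "Annual Precipitation", "mm"),
    Variable("BIO13", "Precipitation of Wettest Month", "mm"),
    Variable("BIO14", "Precipitation of Driest Month", "mm"),
    Variable("BIO15", "Precipitation Seasonality (CV)", "index"),
    Variable("BIO16", "Precipitation of Wettest Quarter", "mm"),
    Variable("BIO17", "Precipitation of Driest Quarter", "mm"),
    Variable("BIO18", "Precipitation of Warmest Quarter", "mm"),
    Variable("BIO19", "Precipitation of Coldest Quarter", "mm"),
)


@dataclass(frozen=True)
class VariableRegistry:
    """Ordered collection of climate variables with unique codes."""

    entries: tuple[Variable, ...] = field(default=BIOCLIM_19)

    def __post_init__(self) -> None:
        codes = [v.code for v in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("variable codes must be unique")
        if not codes:
            raise ValueError("registry must contain at least one variable")

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "VariableRegistry":
        """Subset of the standard 19 variables by code."""
        known = {v.code: v for v in BIOCLIM_19}
        entries = []
        for c in codes:
            if c not in known:
                raise KeyError(f"unknown bioclimatic variable code: {c}")
            entries.append(known[c])
        return cls(tuple(entries))

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(v.code for v in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"unknown variable code: {code}") from None

    def units(self, code: str) -> str:
        return self.entries[self.index(code)].units

    def precipitation_mask(self) -> Sequence[bool]:
        """Which columns carry mm units (these are clamped at 0 when blended)."""
        return [v.units == "mm" for v in self.entries]


DEFAULT_REGISTRY = VariableRegistry()
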