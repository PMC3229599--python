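"""Benthic oxygen-isotope series used to time and weight paleoclimate slices.

δ18O of benthic foraminifera tracks global ice volume / temperature: heavier
values mean colder, more glaciated climate.  The series defines both the set
of reconstruction times (one slice per sample) and, through its modern and
glacial anchor samples, the proportional interpolation weight between the two
end-member climates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Age of the Last Glacial Maximum used to pick the glacial anchor sample.
LGM_AGE_KYA = 21.0


@dataclass
class IsotopeSeries:
    ages_kya: np.ndarray       # strictly increasing, >= 0
    delta18o: np.ndarray       # per mil
    modern_anchor_age: float   # must equal one sample age
    glacial_anchor_age: float  # must equal one sample age

    def __post_init__(self) -> None:
        self.ages_kya = np.asarray(self.ages_kya, dtype=float)
        self.delta18o = np.asarray(self.delta18o, dtype=float)
        if self.ages_kya.ndim != 1 or self.ages_kya.shape != self.delta18o.shape:
            raise ValueError("ages and delta18o must be matching 1-D arrays")
        if np.any(self.ages_kya < 0):
            raise ValueError("ages must be >= 0 kya")
        if np.any(np.diff(self.ages_kya) <= 0):
            raise ValueError("ages must be strictly increasing")
        self.modern_anchor_age = float(self.modern_anchor_age)
        self.glacial_anchor_age = float(self.glacial_anchor_age)
        # anchors must be actual samples with distinct delta values
        d_mod = self.delta_at(self.modern_anchor_age)
        d_gla = self.delta_at(self.glacial_anchor_age)
        if d_mod == d_gla:
            raise ValueError("modern and glacial anchor delta18O values must differ")

    @classmethod
    def from_samples(
        cls,
        ages_kya,
        delta18o,
        modern_anchor_age: float | None = None,
        glacial_anchor_age: float | None = None,
    ) -> "IsotopeSeries":
        """Build a series; anchors default to the samples nearest 0 and 21 kya."""
        ages = np.asarray(ages_kya, dtype=float)
        if modern_anchor_age is None:
            modern_anchor_age = float(ages[np.argmin(np.abs(ages))])
        if glacial_anchor_age is None:
            glacial_anchor_age = float(ages[np.argmin(np.abs(ages - LGM_AGE_KYA))])
        return cls(ages, np.asarray(delta18o, dtype=float),
                   modern_anchor_age, glacial_anchor_age)

    def sample_index(self, age_kya: float, tol: float = 1e-9) -> int:
        """Index of the sample at exactly this age (no sub-sample interpolation)."""
        hits = np.flatnonzero(np.isclose(self.ages_kya, age_kya, rtol=0, atol=tol))
        if len(hits) == 0:
            raise KeyError(f"age {age_kya} kya is not a sample of the isotope series")
        return int(hits[0])

    def delta_at(self, age_kya: float) -> float:
        return float(self.delta18o[self.sample_index(age_kya)])

    @property
    def n_samples(self) -> int:
        return len(self.ages_kya)
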