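"""Age grids and stratum addressing.

The estimation target is the mean intake of one food for every
(country, period, age band, sex) cell. Ages are adult years; bands are
half-open ``[lo, hi)`` with the last band open-ended (80+ by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

ANCHOR_YEARS = (1990, 2010)
SEXES = ("F", "M")

#: Default adult bands: 20-25, 25-35, ..., 75-80, 80+ (8 bands, 2 sexes ->
#: the 16 age/sex cells the model estimates per country-period).
DEFAULT_AGE_EDGES = (20.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 80.0)


class StratumKey(NamedTuple):
    """Address of one age-sex-country-year estimation cell."""

    country: str
    year: int
    age_band: int
    sex: str


@dataclass(frozen=True)
class AgeGrid:
    """Ordered half-open adult age bands; the last band is open-ended.

    ``edges[i]`` is the lower bound of band ``i``; band ``i`` spans
    ``[edges[i], edges[i+1])`` and the final band ``[edges[-1], inf)``.
    ``open_width`` is the nominal width assigned to the open top band for
    population interpolation and for simulating grouped observations.
    """

    edges: tuple[float, ...] = DEFAULT_AGE_EDGES
    open_width: float = 10.0

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 1:
            raise ValueError("age grid needs at least one band")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("age band edges must be strictly increasing")
        if edges[0] < 20:
            raise ValueError("adult age grid must start at >= 20 years")
        if self.open_width <= 0:
            raise ValueError("open_width must be positive")

    @classmethod
    def from_bands(cls, bands: Iterable[tuple[float, float]], open_width: float = 10.0) -> "AgeGrid":
        """Build from explicit (lo, hi) bands, rejecting gaps and overlaps."""
        bands = sorted(bands)
        for (lo1, hi1), (lo2, _hi2) in zip(bands, bands[1:]):
            if not math.isclose(hi1, lo2):
                raise ValueError(f"age bands must be contiguous: gap/overlap between {hi1} and {lo2}")
        return cls(tuple(lo for lo, _ in bands), open_width=open_width)

    @property
    def n_bands(self) -> int:
        return len(self.edges)

    def bounds(self, band: int) -> tuple[float, float]:
        """(lo, hi) of a band; hi is +inf for the top band."""
        lo = self.edges[band]
        hi = self.edges[band + 1] if band + 1 < len(self.edges) else math.inf
        return lo, hi

    def nominal_bounds(self, band: int) -> tuple[float, float]:
        """Finite (lo, hi), giving the open band its nominal width."""
        lo, hi = self.bounds(band)
        if math.isinf(hi):
            hi = lo + self.open_width
        return lo, hi

    @property
    def upper(self) -> float:
        """Nominal upper age of the grid (top edge + open band width)."""
        return self.edges[-1] + self.open_width

    @property
    def midpoints(self) -> tuple[float, ...]:
        return tuple((lo + hi) / 2 for lo, hi in (self.nominal_bounds(i) for i in range(self.n_bands)))

    def overlap_fraction(self, band: int, age_lo: float, age_hi: float) -> float:
        """Fraction of the band's (nominal) span covered by [age_lo, age_hi).

        Population is taken linear-in-age (uniform density) inside a band, so
        this fraction multiplies the band population when a grouped
        observation only partially covers the band.
        """
        lo, hi = self.nominal_bounds(band)
        if math.isinf(age_hi):
            age_hi = max(age_hi if not math.isinf(age_hi) else self.upper, hi)
        ov = min(hi, age_hi) - max(lo, age_lo)
        return max(ov, 0.0) / (hi - lo)

    def bands_overlapping(self, age_lo: float, age_hi: float) -> list[int]:
        return [i for i in range(self.n_bands) if self.overlap_fraction(i, age_lo, age_hi) > 0]
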