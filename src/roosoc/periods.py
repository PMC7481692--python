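"""Analysis periods: calendar years and overlapping two-year windows.

The single-year design aggregates association data per calendar year. The
two-year design uses overlapping windows (A = years 1-2, B = years 2-3,
C = years 3-4, ...) whose binomial responses relate to the second year only,
so no young is counted in two windows.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class Period:
    label: str
    years: tuple[int, ...]

    @property
    def response_year(self) -> int:
        """Year whose reproductive outcomes the period's model row uses."""
        return self.years[-1]

    def contains(self, ts) -> bool:
        return pd.Timestamp(ts).year in self.years

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.label}({self.years[0]}-{self.years[-1]})"


def annual_periods(years: list[int]) -> list[Period]:
    return [Period(str(y), (y,)) for y in sorted(years)]


def window_periods(years: list[int]) -> list[Period]:
    """Overlapping 2-year windows labelled A, B, C, ... over sorted years."""
    ys = sorted(years)
    labels = string.ascii_uppercase
    return [Period(labels[i], (y0, y1)) for i, (y0, y1) in enumerate(zip(ys, ys[1:]))]


def observed_years(observations: pd.DataFrame) -> list[int]:
    return sorted(pd.to_datetime(observations["date"]).dt.year.unique().tolist())
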