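"""Master age grid and the day-to-bin discretisation convention.

Continuous age (in days since birth) is discretised into equal-width bins
before any correlation is estimated; correlations are assumed stable within
a bin.  The default grid is weekly over ages 0-6570 days (birth to 18
years), which yields a 940-bin grid and hence a 940x940 combined
correlation matrix.

The binning convention is ``bin = round(age_days / bin_width_days)`` with
ties-to-even.  A bin ``b`` therefore collects the days closest to
``b * bin_width_days``, which makes ``b * bin_width_days`` the natural
representative age of the bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AgeGrid", "day_to_bin", "AgeRangeError"]


class AgeRangeError(ValueError):
    """An age falls outside the grid's closed day range."""


@dataclass(frozen=True)
class AgeGrid:
    """An equal-width discretisation of a closed age range in days.

    Parameters
    ----------
    min_day, max_day : int
        Closed range of ages covered, in integer days (birth = day 0).
    bin_width_days : int
        Width of each bin; 7 (weekly) by default.

    Notes
    -----
    Bin indices run from ``round(min_day / w)`` to ``round(max_day / w)``
    inclusive, so the default grid (0-6570 days, weekly) has exactly
    940 bins.
    """

    min_day: int = 0
    max_day: int = 6570
    bin_width_days: int = 7

    def __post_init__(self) -> None:
        if self.min_day < 0:
            raise ValueError(f"min_day must be >= 0, got {self.min_day}")
        if self.max_day <= self.min_day:
            raise ValueError("max_day must exceed min_day")
        if self.bin_width_days < 1:
            raise ValueError("bin_width_days must be a positive integer")

    @property
    def first_bin(self) -> int:
        return int(round(self.min_day / self.bin_width_days))

    @property
    def last_bin(self) -> int:
        return int(round(self.max_day / self.bin_width_days))

    @property
    def n_bins(self) -> int:
        return self.last_bin - self.first_bin + 1

    @property
    def bins(self) -> np.ndarray:
        """Consecutive integer bin indices covering the range."""
        return np.arange(self.first_bin, self.last_bin + 1)

    @property
    def representative_age(self) -> np.ndarray:
        """Per-bin representative age in days (= bin_width_days * bin).

        Under round-to-nearest binning this is the centre of the day
        range mapped to each bin.
        """
        return self.bins * self.bin_width_days

    def contains(self, age_days) -> np.ndarray:
        age = np.asarray(age_days)
        return (age >= self.min_day) & (age <= self.max_day)

    def to_dict(self) -> dict:
        return {
            "min_day": self.min_day,
            "max_day": self.max_day,
            "bin_width_days": self.bin_width_days,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgeGrid":
        return cls(int(d["min_day"]), int(d["max_day"]), int(d["bin_width_days"]))


def day_to_bin(age_days, grid: AgeGrid | None = None):
    """Map age in days to a grid bin index: ``round(age / width)``, ties-to-even.

    Accepts scalars or arrays.  Raises :class:`AgeRangeError` if any age
    lies outside the grid's closed ``[min_day, max_day]`` range.
    """
    if grid is None:
        grid = AgeGrid()
    age = np.asarray(age_days)
    inside = grid.contains(age)
    if not np.all(inside):
        bad = np.atleast_1d(age)[~np.atleast_1d(inside)]
        raise AgeRangeError(
            f"age(s) {bad[:5].tolist()} outside grid range "
            f"[{grid.min_day}, {grid.max_day}] days"
        )
    bins = np.round(age / grid.bin_width_days).astype(int)
    if np.isscalar(age_days) or bins.ndim == 0:
        return int(bins)
    return bins
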