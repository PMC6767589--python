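"""Conditional standard deviation scores (cSDS): growth velocity.

A child's change in z-score between two ages overstates faltering or
catch-up for children who start far from the mean (regression to the
mean).  Under a bivariate-normal model with correlation ``r12`` between
the two ages, the standardized residual of the second score given the
first,

    Z_{2|1} = (Z2 - r12 * Z1) / sqrt(1 - r12^2),

has mean 0 and variance 1 in a reference population, so it is a
velocity score already corrected for where the child started.  The
correlation ``r12`` for any pair of ages is looked up from a smooth
combined correlation matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SmoothCorrelationMatrix
from .grid import day_to_bin

log = logging.getLogger("growthcorr")

__all__ = ["VelocityScore", "csds", "lookup_r", "dynamic_csds", "csds_table"]


@dataclass(frozen=True)
class VelocityScore:
    """One cSDS value together with the inputs that produced it."""

    t1: int
    t2: int
    Z1: float
    Z2: float
    r12: float
    csds: float


def csds(Z1, Z2, r12):
    """Conditional SDS ``(Z2 - r12*Z1) / sqrt(1 - r12^2)``.

    Accepts scalars or arrays; requires ``|r12| < 1`` and finite scores.
    """
    Z1 = np.asarray(Z1, dtype=float)
    Z2 = np.asarray(Z2, dtype=float)
    r = np.asarray(r12, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("csds requires |r12| < 1")
    if not (np.isfinite(Z1).all() and np.isfinite(Z2).all()):
        raise ValueError("z-scores must be finite")
    out = (Z2 - r * Z1) / np.sqrt(1.0 - r * r)
    return float(out) if out.ndim == 0 else out


def lookup_r(matrix: SmoothCorrelationMatrix, t1_days, t2_days) -> float:
    """Correlation between two ages from the combined matrix.

    Symmetric in its age arguments; ages are mapped to grid bins with
    the matrix's own discretisation convention.
    """
    b1 = day_to_bin(t1_days, matrix.grid) - matrix.grid.first_bin
    b2 = day_to_bin(t2_days, matrix.grid) - matrix.grid.first_bin
    return float(matrix.rho[b1, b2])


def dynamic_csds(series, matrix: SmoothCorrelationMatrix) -> list[VelocityScore]:
    """cSDS between each pair of consecutive observations of one child.

    ``series`` is a list of ``(age_days, z)`` sorted by age with at
    least two entries.  Consecutive observations that fall in the same
    age bin (correlation 1, undefined score) are skipped with a warning.
    """
    if len(series) < 2:
        raise ValueError("need at least two observations")
    ages = [t for t, _ in series]
    if any(b < a for a, b in zip(ages, ages[1:])):
        raise ValueError("series must be sorted by age")
    out = []
    for (t1, z1), (t2, z2) in zip(series, series[1:]):
        b1 = day_to_bin(t1, matrix.grid)
        b2 = day_to_bin(t2, matrix.grid)
        if b1 == b2:
            log.warning("consecutive observations at ages %s and %s fall in "
                        "the same bin; pair skipped", t1, t2)
            continue
        r = lookup_r(matrix, t1, t2)
        out.append(VelocityScore(int(t1), int(t2), float(z1), float(z2),
                                 r, csds(z1, z2, r)))
    return out


def csds_table(children, matrix: SmoothCorrelationMatrix | None = None
               ) -> pd.DataFrame:
    """cSDS for a list of children, one (first, last) observation pair each.

    ``children`` rows are ``(id, t1, t2, Z1, Z2)`` or, when the
    correlation is already known, ``(id, t1, t2, Z1, Z2, r12)``; without
    an explicit ``r12`` a matrix is required for the lookup.  Per-row
    failures (e.g. an age outside the matrix range) are collected in the
    ``error`` column rather than raised.
    """
    rows = []
    for row in children:
        rec = dict(zip(("child", "t1", "t2", "Z1", "Z2", "r12"), row))
        err = ""
        try:
            if rec.get("r12") is None:
                if matrix is None:
                    raise ValueError("no r12 given and no matrix to look it up")
                rec["r12"] = lookup_r(matrix, rec["t1"], rec["t2"])
            rec["csds"] = csds(rec["Z1"], rec["Z2"], rec["r12"])
        except Exception as exc:  # noqa: BLE001 - collected per row
            rec["csds"] = math.nan
            err = str(exc)
        rec["error"] = err
        rows.append(rec)
    return pd.DataFrame(rows, columns=["child", "t1", "t2", "Z1", "Z2",
                                       "r12", "csds", "error"])
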