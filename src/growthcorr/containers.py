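"""Matrix containers passed between pipeline stages.

All three containers hold square age-by-age matrices indexed by master-grid
bins, plus stage-specific layers (effective sample sizes, CI bounds,
study counts, missingness masks).  They share a layered representation so
one reader/writer (:mod:`growthcorr.io`) serves every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import AgeGrid

__all__ = [
    "GrowthRecordSet",
    "StudyCorrelation",
    "RawCombinedSurface",
    "SmoothCorrelationMatrix",
    "IntegrityError",
]


class IntegrityError(ValueError):
    """A container violates one of its structural invariants."""


def _check_square(name: str, a: np.ndarray, n: int) -> None:
    if a.shape != (n, n):
        raise IntegrityError(f"layer {name!r} has shape {a.shape}, expected {(n, n)}")


def _check_symmetric(name: str, a: np.ndarray) -> None:
    if not np.array_equal(a, a.T):
        raise IntegrityError(f"layer {name!r} is not exactly symmetric")


@dataclass
class GrowthRecordSet:
    """Long-format visit records for one study.

    ``records`` is a pandas DataFrame with columns ``child`` (id),
    ``age_days`` (int, >= 0), ``z`` (finite float) and ``measure``
    ("HAZ" or "WAZ").  Each (child, age_days, measure) triple is unique.
    """

    study_id: str
    records: "object"  # pandas.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = {"child", "age_days", "z", "measure"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        if len(df) and not np.isfinite(df["z"].to_numpy(float)).all():
            raise ValueError("non-finite z-scores in record set")
        if len(df) and (df["age_days"].to_numpy() < 0).any():
            raise ValueError("negative ages in record set")
        if df.duplicated(["child", "age_days", "measure"]).any():
            raise ValueError("duplicate (child, age_days, measure) rows")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_children(self) -> int:
        return self.records["child"].nunique()

    def for_measure(self, measure: str) -> "GrowthRecordSet":
        sub = self.records[self.records["measure"] == measure].reset_index(drop=True)
        return GrowthRecordSet(self.study_id, sub)


@dataclass
class StudyCorrelation:
    """One study's smooth correlation matrix on its covered master-grid bins.

    ``corr`` is s x s symmetric with exact unit diagonal; ``n_eff[i, j]``
    counts children observed in both bin i and bin j; ``mask`` is True
    where the entry is usable (enough children, positive variance).
    """

    study_id: str
    grid: AgeGrid
    bins: np.ndarray           # (s,) master bin indices covered
    corr: np.ndarray           # (s, s)
    n_eff: np.ndarray          # (s, s) int
    mask: np.ndarray           # (s, s) bool
    n_children: int

    kind = "study_correlation"

    def __post_init__(self) -> None:
        s = len(self.bins)
        for name in ("corr", "n_eff", "mask"):
            _check_square(name, getattr(self, name), s)
        _check_symmetric("corr", self.corr)
        if not np.all(np.diag(self.corr) == 1.0):
            raise IntegrityError("study correlation diagonal is not exactly 1")
        if np.any(np.abs(self.corr[self.mask]) > 1.0):
            raise IntegrityError("correlation entries outside [-1, 1]")
        if np.any(self.n_eff > self.n_children):
            raise IntegrityError("n_eff exceeds the study's child count")

    def to_layers(self):
        attrs = {
            "kind": self.kind,
            "study_id": self.study_id,
            "n_children": int(self.n_children),
        }
        layers = {
            "corr": self.corr,
            "n_eff": self.n_eff.astype(np.int64),
            "mask": self.mask.astype(np.uint8),
        }
        return self.grid, self.bins, layers, attrs

    @classmethod
    def from_layers(cls, grid, bins, layers, attrs):
        return cls(
            study_id=attrs["study_id"],
            grid=grid,
            bins=np.asarray(bins),
            corr=layers["corr"],
            n_eff=layers["n_eff"].astype(np.int64),
            mask=layers["mask"].astype(bool),
            n_children=int(attrs["n_children"]),
        )


@dataclass
class RawCombinedSurface:
    """Stage-1 meta-analysed surface on the full master grid.

    Entries exist (``mask`` True) only where at least one study covers
    the bin pair; ``count`` records how many studies contributed to each
    entry.  Estimates and CI bounds are on the correlation scale;
    ``fisher_mean``, ``tau2`` and ``se`` live on the Fisher-z scale.
    """

    grid: AgeGrid
    estimate: np.ndarray
    fisher_mean: np.ndarray
    tau2: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    count: np.ndarray
    mask: np.ndarray
    ci_level: float = 0.95
    measure: str = ""

    kind = "raw_combined_surface"

    def __post_init__(self) -> None:
        r = self.grid.n_bins
        for name in ("estimate", "fisher_mean", "tau2", "se",
                     "lower", "upper", "count", "mask"):
            a = getattr(self, name)
            _check_square(name, a, r)
            _check_symmetric(name, a)
        if not np.array_equal(self.mask, self.count > 0):
            raise IntegrityError("mask and count layers disagree")
        m = self.mask
        if np.any(self.lower[m] > self.estimate[m]) or np.any(self.estimate[m] > self.upper[m]):
            raise IntegrityError("CI bounds do not bracket the estimate")

    @property
    def bins(self) -> np.ndarray:
        return self.grid.bins

    def to_layers(self):
        attrs = {
            "kind": self.kind,
            "ci_level": float(self.ci_level),
            "measure": self.measure,
        }
        layers = {
            "estimate": self.estimate,
            "fisher_mean": self.fisher_mean,
            "tau2": self.tau2,
            "se": self.se,
            "lower": self.lower,
            "upper": self.upper,
            "count": self.count.astype(np.int64),
            "mask": self.mask.astype(np.uint8),
        }
        return self.grid, self.bins, layers, attrs

    @classmethod
    def from_layers(cls, grid, bins, layers, attrs):
        return cls(
            grid=grid,
            estimate=layers["estimate"],
            fisher_mean=layers["fisher_mean"],
            tau2=layers["tau2"],
            se=layers["se"],
            lower=layers["lower"],
            upper=layers["upper"],
            count=layers["count"].astype(np.int64),
            mask=layers["mask"].astype(bool),
            ci_level=float(attrs.get("ci_level", 0.95)),
            measure=attrs.get("measure", ""),
        )


@dataclass
class SmoothCorrelationMatrix:
    """Stage-2 final correlation matrix: complete, symmetric, unit diagonal.

    ``lower``/``upper`` are the smoothed CI surfaces and ``uncertainty``
    their difference (floored at zero).  ``fit_meta`` records the chosen
    smoothing parameter, basis size and effective degrees of freedom.
    """

    grid: AgeGrid
    rho: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    uncertainty: np.ndarray
    fit_meta: dict = field(default_factory=dict)
    measure: str = ""

    kind = "smooth_correlation_matrix"

    def __post_init__(self) -> None:
        r = self.grid.n_bins
        for name in ("rho", "lower", "upper", "uncertainty"):
            a = getattr(self, name)
            _check_square(name, a, r)
            if not np.isfinite(a).all():
                raise IntegrityError(f"layer {name!r} contains non-finite entries")
        _check_symmetric("rho", self.rho)
        if not np.all(np.diag(self.rho) == 1.0):
            raise IntegrityError("final matrix diagonal is not exactly 1")
        off = ~np.eye(r, dtype=bool)
        if np.any(np.abs(self.rho[off]) >= 1.0):
            raise IntegrityError("off-diagonal entries outside (-1, 1)")
        if np.any(self.uncertainty < 0):
            raise IntegrityError("negative uncertainty entries")

    @property
    def bins(self) -> np.ndarray:
        return self.grid.bins

    def to_layers(self):
        attrs = {"kind": self.kind, "measure": self.measure,
                 "fit_meta": dict(self.fit_meta)}
        layers = {
            "rho": self.rho,
            "lower": self.lower,
            "upper": self.upper,
            "uncertainty": self.uncertainty,
        }
        return self.grid, self.bins, layers, attrs

    @classmethod
    def from_layers(cls, grid, bins, layers, attrs):
        return cls(
            grid=grid,
            rho=layers["rho"],
            lower=layers["lower"],
            upper=layers["upper"],
            uncertainty=layers["uncertainty"],
            fit_meta=dict(attrs.get("fit_meta", {})),
            measure=attrs.get("measure", ""),
        )


CONTAINER_KINDS = {
    StudyCorrelation.kind: StudyCorrelation,
    RawCombinedSurface.kind: RawCombinedSurface,
    SmoothCorrelationMatrix.kind: SmoothCorrelationMatrix,
}
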