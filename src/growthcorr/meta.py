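"""Stage 1: elementwise random-effects meta-analysis of study correlations.

Every study matrix is first aligned to the master grid (entries outside
the study's covered bins are missing).  Each grid entry (i, j) is then
pooled across the studies that cover it: correlations are moved to the
Fisher-z scale, where the sampling variance of a correlation from
``n`` paired observations is approximately ``1/(n - 3)``; between-study
heterogeneity tau^2 is estimated per entry by DerSimonian-Laird; and
the pooled mean is the inverse-variance weighted average with weights
``1/(sigma^2 + tau^2)``.  Back-transforming the pooled mean and its
normal-theory CI endpoints gives the rough combined correlation surface,
which is incomplete wherever no study covers an age pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .containers import RawCombinedSurface, StudyCorrelation
from .grid import AgeGrid

log = logging.getLogger("growthcorr")

__all__ = [
    "fisher_z",
    "inverse_fisher",
    "fisher_variance",
    "entry_meta",
    "AlignedStudySet",
    "align_studies",
    "combine_matrices",
]

#: Correlations are clipped to +/- this before the Fisher transform.
CORR_CLIP = 0.999


def fisher_z(rho):
    """Fisher variance-stabilizing transform atanh(rho) = 0.5 ln((1+rho)/(1-rho)).

    Strictly increasing and odd; raises on ``|rho| >= 1`` (upstream
    clipping at 0.999 should prevent that).
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("fisher_z requires |rho| < 1")
    out = np.arctanh(rho)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z):
    """Inverse Fisher transform tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def fisher_variance(n_eff):
    """Large-sample variance 1/(n - 3) of a Fisher-transformed correlation.

    Returns NaN (a masked entry, not an exception) where ``n_eff <= 3``.
    """
    n = np.asarray(n_eff, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(n > 3, 1.0 / (n - 3.0), np.nan)
    return float(v) if v.ndim == 0 else v


def entry_meta(values, variances):
    """Random-effects pool of one entry across studies (DerSimonian-Laird).

    ``tau^2 = max(0, (Q - (K-1)) / C)`` with fixed-effect weights
    ``w0 = 1/sigma^2``, ``Q = sum w0 (f - fbar)^2`` and
    ``C = sum w0 - sum w0^2 / sum w0``; the pooled mean then uses
    ``w = 1/(sigma^2 + tau^2)``.  Returns ``(mean, se, tau2)``; a single
    study passes through as ``(f, sigma, 0)``; empty input returns NaNs
    (a missing entry).
    """
    f = np.asarray(values, dtype=float)
    v = np.asarray(variances, dtype=float)
    if f.shape != v.shape or f.ndim != 1:
        raise ValueError("values and variances must be equal-length 1-d")
    if f.size == 0:
        return (np.nan, np.nan, np.nan)
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    if f.size == 1:
        return (float(f[0]), float(np.sqrt(v[0])), 0.0)
    w0 = 1.0 / v
    sw0 = w0.sum()
    fbar = (w0 * f).sum() / sw0
    Q = (w0 * (f - fbar) ** 2).sum()
    C = sw0 - (w0 ** 2).sum() / sw0
    tau2 = max(0.0, (Q - (f.size - 1)) / C)
    w = 1.0 / (v + tau2)
    mean = (w * f).sum() / w.sum()
    se = 1.0 / np.sqrt(w.sum())
    return (float(mean), float(se), float(tau2))


@dataclass
class AlignedStudySet:
    """Study matrices stacked on the master grid with aligned missingness.

    All layers have shape (K, r, r); ``present`` is True where a study
    provides a usable entry (covered bins, unmasked, n_eff > 3), and the
    ``fisher`` and ``variance`` layers are populated exactly there.
    """

    grid: AgeGrid
    study_ids: list
    corr: np.ndarray      # (K, r, r)
    fisher: np.ndarray    # (K, r, r)
    variance: np.ndarray  # (K, r, r)
    n_eff: np.ndarray     # (K, r, r)
    present: np.ndarray   # (K, r, r) bool

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)


def align_studies(studies: list[StudyCorrelation], grid: AgeGrid | None = None
                  ) -> AlignedStudySet:
    """Embed each study matrix into the full master grid.

    Entries are present only on the study's covered bin block; entries
    the study masked, or with effective sample size <= 3 (undefined
    Fisher variance), stay missing.
    """
    if not studies:
        raise ValueError("need at least one study")
    if grid is None:
        grid = studies[0].grid
    r = grid.n_bins
    K = len(studies)
    corr = np.zeros((K, r, r))
    fisher = np.zeros((K, r, r))
    variance = np.ones((K, r, r))
    n_eff = np.zeros((K, r, r), dtype=np.int64)
    present = np.zeros((K, r, r), dtype=bool)
    for k, st in enumerate(studies):
        if st.grid.to_dict() != grid.to_dict():
            raise ValueError(f"{st.study_id}: grid mismatch")
        loc = st.bins - grid.first_bin
        block = np.ix_([k], loc, loc)
        ok = st.mask & (st.n_eff > 3)
        c = np.clip(st.corr, -CORR_CLIP, CORR_CLIP)
        corr[block] = np.where(ok, c, 0.0)
        fisher[block] = np.where(ok, np.arctanh(np.where(ok, c, 0.0)), 0.0)
        with np.errstate(divide="ignore"):
            v = np.where(ok, 1.0 / np.maximum(st.n_eff - 3.0, 1e-300), 1.0)
        variance[block] = v
        n_eff[block] = st.n_eff
        present[block] = ok
    return AlignedStudySet(grid, [s.study_id for s in studies],
                           corr, fisher, variance, n_eff, present)


def combine_matrices(aligned: AlignedStudySet, ci_level: float = 0.95,
                     shared_tau2: bool = False, measure: str = ""
                     ) -> RawCombinedSurface:
    """Pool aligned study matrices entry by entry on the Fisher scale.

    Each entry uses only the studies that cover it; entries no study
    covers stay missing (mask 0, count 0) for stage 2 to fill.  By
    default tau^2 is estimated per entry; ``shared_tau2`` pools a single
    tau^2 over all observed entries instead.
    """
    p = aligned.present
    f = aligned.fisher
    v = aligned.variance
    count = p.sum(axis=0)
    mask = count > 0
    if not mask.any():
        log.warning("no entry is covered by any study: all-missing surface")

    with np.errstate(divide="ignore", invalid="ignore"):
        w0 = np.where(p, 1.0 / v, 0.0)
        sw0 = w0.sum(axis=0)
        fbar = np.where(mask, (w0 * f).sum(axis=0) / np.where(mask, sw0, 1.0), 0.0)
        Q = (w0 * np.where(p, (f - fbar) ** 2, 0.0)).sum(axis=0)
        C = sw0 - (w0 ** 2).sum(axis=0) / np.where(sw0 > 0, sw0, 1.0)
        multi = count >= 2
        tau2 = np.zeros_like(Q)
        tau2[multi] = np.maximum(0.0, (Q[multi] - (count[multi] - 1)) / C[multi])
        if shared_tau2:
            tau2[:] = float(np.mean(tau2[multi])) if multi.any() else 0.0
            tau2[~mask] = 0.0
        w = np.where(p, 1.0 / (v + tau2[None, :, :]), 0.0)
        sw = w.sum(axis=0)
        m = np.where(mask, (w * f).sum(axis=0) / np.where(mask, sw, 1.0), 0.0)
        se = np.where(mask, 1.0 / np.sqrt(np.where(mask, sw, 1.0)), 0.0)

    zcrit = float(norm.ppf(0.5 + ci_level / 2.0))
    est = np.where(mask, np.tanh(m), 0.0)
    lower = np.where(mask, np.tanh(m - zcrit * se), 0.0)
    upper = np.where(mask, np.tanh(m + zcrit * se), 0.0)

    return RawCombinedSurface(
        grid=aligned.grid,
        estimate=est,
        fisher_mean=m,
        tau2=np.where(mask, tau2, 0.0),
        se=se,
        lower=lower,
        upper=upper,
        count=count.astype(np.int64),
        mask=mask,
        ci_level=ci_level,
        measure=measure,
    )
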