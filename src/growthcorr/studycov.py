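"""Smooth correlation matrices for single sparse longitudinal studies.

A study observes each child's z-score at irregular ages.  The study's
age-by-age correlation matrix is estimated in the functional-data style:

1. fit a smooth penalized-spline mean function mu(t) to all (age, z)
   points and form residuals e = z - mu(age);
2. for every child, form the cross-products e_i * e_j over all ordered
   pairs of *distinct* visits (same-visit squares are kept apart: they
   carry the measurement-error nugget and would bias the diagonal);
3. smooth the cross-products over the (age_i, age_j) plane with a
   symmetric tensor-product P-spline, giving a smooth covariance
   surface whose diagonal is the nugget-free process variance;
4. normalize to a correlation matrix, and attach per-entry effective
   sample sizes (children observed in both bins) and a missingness mask.

This is a generic penalized-spline covariance smoother in the sandwich
-smoother tradition, not a reimplementation of any specific estimator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._pspline import CannotFitError, PSpline1D, SymmetricSurfaceSmoother
from .containers import GrowthRecordSet, StudyCorrelation
from .grid import AgeGrid, day_to_bin

log = logging.getLogger("growthcorr")

__all__ = [
    "MeanFunction",
    "fit_mean_function",
    "empirical_cross_products",
    "smooth_covariance_surface",
    "study_correlation",
    "InsufficientDataError",
]

#: Minimum children observed in both bins for a correlation entry to be kept.
N_MIN_DEFAULT = 10
#: Diagonal variance below this is treated as degenerate and masked.
VARIANCE_FLOOR = 1e-8
#: Off-diagonal correlations are clipped to +/- this before any Fisher step.
CORR_CLIP = 0.999


class InsufficientDataError(ValueError):
    """Too few observations (or degenerate ages) to fit a study model."""


class MeanFunction:
    """Smooth study-specific mean z-score as a function of age in days."""

    def __init__(self, study_id: str, spline: PSpline1D):
        self.study_id = study_id
        self._spline = spline

    def __call__(self, age_days):
        return self._spline(age_days)

    @property
    def lambda_(self) -> float:
        return self._spline.lambda_

    @property
    def edf(self) -> float:
        return self._spline.edf_


def fit_mean_function(records: GrowthRecordSet, lambda_mu="auto",
                      n_basis: int = 35) -> MeanFunction:
    """Penalized B-spline regression of z on age for one study.

    Requires at least 20 observations spanning at least 2 distinct ages.
    """
    df = records.records
    if len(df) < 20:
        raise InsufficientDataError(
            f"{records.study_id}: {len(df)} observations; need >= 20"
        )
    ages = df["age_days"].to_numpy(float)
    if np.unique(ages).size < 2:
        raise InsufficientDataError(
            f"{records.study_id}: all observations at a single age"
        )
    sp = PSpline1D(n_basis=n_basis).fit(ages, df["z"].to_numpy(float), lam=lambda_mu)
    return MeanFunction(records.study_id, sp)


def empirical_cross_products(records: GrowthRecordSet, mean: MeanFunction):
    """Residual cross-products over ordered pairs of distinct visits.

    Returns ``(pairs, variance_stream)``: ``pairs`` has columns
    ``age_i, age_j, product, child`` with one row per ordered pair of
    distinct visits of the same child; ``variance_stream`` has columns
    ``age, square, child`` holding the same-visit squared residuals,
    which include the measurement-error nugget and are deliberately kept
    out of the covariance smoothing.
    """
    df = records.records
    resid = df["z"].to_numpy(float) - mean(df["age_days"].to_numpy(float))
    ages = df["age_days"].to_numpy(float)
    codes = pd.factorize(df["child"].to_numpy())[0]
    order = np.argsort(codes, kind="stable")
    resid, ages, codes = resid[order], ages[order], codes[order]
    child_labels = df["child"].to_numpy()[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    bounds = np.r_[starts, codes.size]
    ai, aj, prod, who = [], [], [], []
    for s, e in zip(bounds[:-1], bounds[1:]):
        v = e - s
        if v < 2:
            continue
        r, a = resid[s:e], ages[s:e]
        off = ~np.eye(v, dtype=bool)
        ai.append(np.broadcast_to(a[:, None], (v, v))[off])
        aj.append(np.broadcast_to(a[None, :], (v, v))[off])
        prod.append(np.outer(r, r)[off])
        who.append(np.repeat(child_labels[s], v * (v - 1)))
    if ai:
        pairs = pd.DataFrame({
            "age_i": np.concatenate(ai),
            "age_j": np.concatenate(aj),
            "product": np.concatenate(prod),
            "child": np.concatenate(who),
        })
    else:
        pairs = pd.DataFrame(columns=["age_i", "age_j", "product", "child"])
    variance_stream = pd.DataFrame({
        "age": ages, "square": resid ** 2, "child": child_labels,
    })
    return pairs, variance_stream


#: Cross-products are aggregated at this fine resolution (in days) before
#: smoothing, independent of the output grid.  Coarse aggregation would
#: place within-cell pairs (mean separation ~ cell width / 3) at lag-0
#: coordinates and bias the fitted diagonal variance low, inflating every
#: correlation; weekly aggregation keeps that bias negligible.
FIT_BIN_DAYS = 7


def smooth_covariance_surface(pairs: pd.DataFrame, grid_bins: np.ndarray,
                              grid: AgeGrid, lambda_c="auto",
                              n_basis: int | None = None,
                              fit_bin_days: int = FIT_BIN_DAYS):
    """Symmetric P-spline fit to cross-products, evaluated on the study bins.

    Products are averaged within fine (weekly by default) age-pair cells
    and the cell means smoothed in age-day coordinates with cell counts
    as weights; the fitted surface is then evaluated at the output
    grid's representative ages.  Returns ``(cov, info)`` where ``cov``
    is the s x s smooth covariance matrix on ``grid_bins``.
    """
    if len(pairs) == 0:
        raise CannotFitError("no cross-products: no child has two visits")
    grid_bins = np.asarray(grid_bins)
    s = grid_bins.size
    ai = pairs["age_i"].to_numpy(float)
    aj = pairs["age_j"].to_numpy(float)
    # fine aggregation cells in day coordinates
    fi = np.round(ai / fit_bin_days).astype(np.int64)
    fj = np.round(aj / fit_bin_days).astype(np.int64)
    f0, f1 = min(fi.min(), fj.min()), max(fi.max(), fj.max())
    nf = int(f1 - f0 + 1)
    flat = (fi - f0) * nf + (fj - f0)
    count = np.bincount(flat, minlength=nf * nf)
    total = np.bincount(flat, weights=pairs["product"].to_numpy(),
                        minlength=nf * nf)
    obs = np.flatnonzero(count)
    cell_mean = total[obs] / count[obs]
    ci = (obs // nf + f0) * float(fit_bin_days)
    cj = (obs % nf + f0) * float(fit_bin_days)
    if n_basis is None:
        # scale the marginal basis with the study's age span at the
        # fitting resolution (not the output grid): the near-diagonal
        # apex of the covariance surface must stay resolvable
        span_cells = nf
        n_basis = min(35, max(4, span_cells // 2))
    out_ages = grid_bins.astype(float) * grid.bin_width_days
    lo = min(out_ages.min(), ci.min(), cj.min())
    hi = max(out_ages.max(), ci.max(), cj.max())
    smoother = SymmetricSurfaceSmoother(out_ages, n_basis=n_basis,
                                        domain=(lo, hi))
    try:
        res = smoother.fit_points(ci, cj, cell_mean,
                                  weights=count[obs].astype(float),
                                  lam=lambda_c)
    except np.linalg.LinAlgError as exc:
        raise CannotFitError(
            "rank-deficient covariance design; coarsen the knot grid"
        ) from exc
    cov = smoother.evaluate(res["coef"])
    return cov, res


def _coverage_counts(records: GrowthRecordSet, grid_bins: np.ndarray,
                     grid: AgeGrid) -> np.ndarray:
    """n_eff[i, j] = number of children with >= 1 visit in bin i AND bin j."""
    df = records.records
    bins = day_to_bin(df["age_days"].to_numpy(), grid) - grid_bins[0]
    codes = pd.factorize(df["child"].to_numpy())[0]
    inc = np.zeros((codes.max() + 1, grid_bins.size), dtype=np.int64)
    inc[codes, bins] = 1
    return inc.T @ inc


def study_correlation(records: GrowthRecordSet, grid: AgeGrid | None = None,
                      lambda_mu="auto", lambda_c="auto",
                      n_min: int = N_MIN_DEFAULT,
                      n_basis: int | None = None) -> StudyCorrelation:
    """Estimate one study's smooth correlation matrix on the master grid.

    Output entries are masked where fewer than ``n_min`` children were
    observed in both bins or the smoothed variance falls below the
    degeneracy floor.  Off-diagonal correlations are clipped to
    +/-0.999; the diagonal is exactly 1.
    """
    if grid is None:
        grid = AgeGrid()
    df = records.records
    inside = grid.contains(df["age_days"].to_numpy())
    if not inside.all():
        log.warning("%s: dropping %d records outside the grid range",
                    records.study_id, int((~inside).sum()))
        records = GrowthRecordSet(records.study_id,
                                  df[inside].reset_index(drop=True))
        df = records.records
    if df.empty:
        raise InsufficientDataError(f"{records.study_id}: no records on the grid")

    obs_bins = day_to_bin(df["age_days"].to_numpy(), grid)
    grid_bins = np.arange(obs_bins.min(), obs_bins.max() + 1)
    s = grid_bins.size
    if s < 2:
        raise InsufficientDataError(
            f"{records.study_id}: observations span a single age bin"
        )

    mean = fit_mean_function(records, lambda_mu=lambda_mu)
    pairs, _ = empirical_cross_products(records, mean)
    cov, info = smooth_covariance_surface(pairs, grid_bins, grid,
                                          lambda_c=lambda_c, n_basis=n_basis)

    d = np.diag(cov).copy()
    valid = d > VARIANCE_FLOOR
    denom = np.sqrt(np.where(valid, d, 1.0))
    corr = cov / np.outer(denom, denom)
    corr = (corr + corr.T) / 2.0
    corr = np.clip(corr, -CORR_CLIP, CORR_CLIP)
    np.fill_diagonal(corr, 1.0)
    corr[~valid, :] = 0.0
    corr[:, ~valid] = 0.0
    np.fill_diagonal(corr, 1.0)

    n_eff = _coverage_counts(records, grid_bins, grid)
    mask = (n_eff >= n_min) & np.outer(valid, valid)
    n_masked = int((~mask).sum())
    if n_masked:
        log.info("%s: %d of %d entries masked (n_eff < %d or degenerate variance)",
                 records.study_id, n_masked, mask.size, n_min)

    return StudyCorrelation(
        study_id=records.study_id,
        grid=grid,
        bins=grid_bins,
        corr=corr,
        n_eff=n_eff,
        mask=mask,
        n_children=records.n_children,
    )
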