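"""Stage 2: smooth the incomplete meta-analysed surface into a valid matrix.

The stage-1 surface is noisy (each entry was pooled independently) and
incomplete (no study covers some age pairs).  Both problems are fixed by
one bivariate penalized-spline fit on the Fisher scale: the unit
diagonal is removed first (it is an artefact, not data), the observed
off-diagonal cells are smoothed with a symmetry-constrained tensor-
product P-spline, the fit is evaluated on every cell of the grid, and
the result is back-transformed and renormalized,
``rho_tilde[i,j] = rho_hat[i,j] / sqrt(rho_hat[i,i] * rho_hat[j,j])``,
so the final matrix is complete, symmetric, and has an exact unit
diagonal.  The same smoother, applied to the stage-1 CI bounds, yields
smoothed confidence surfaces and their difference, the uncertainty
surface.
"""

from __future__ import annotations

import logging

import numpy as np
from statsmodels.stats.correlation_tools import corr_nearest

from ._pspline import CannotFitError, SymmetricSurfaceSmoother
from .containers import RawCombinedSurface, SmoothCorrelationMatrix
from .grid import AgeGrid

log = logging.getLogger("growthcorr")

__all__ = [
    "to_fisher_surface",
    "symmetric_pspline_fit",
    "diagonal_limit",
    "finalize_correlation",
    "smooth_ci_surfaces",
    "smooth_surface",
    "nearest_psd_projection",
    "NormalizationError",
]

CORR_CLIP = 0.999
#: Inverse-variance cell weights are capped at this quantile so a few
#: very dense cells cannot dominate the surface fit.
WEIGHT_CAP_QUANTILE = 0.95


class NormalizationError(RuntimeError):
    """The smoothed surface has a non-positive diagonal value."""


def to_fisher_surface(raw: RawCombinedSurface, weighted: bool = True,
                      weight_cap_quantile: float = WEIGHT_CAP_QUANTILE):
    """Fisher-transform the stage-1 estimates and prepare smoothing inputs.

    Diagonal cells are masked regardless of coverage (their value is the
    trivial 1), and weights are inverse squared meta-analytic standard
    errors, capped at the given quantile; ``weighted=False`` gives the
    homoscedastic working model (unit weights).
    """
    r = raw.grid.n_bins
    mask = raw.mask & ~np.eye(r, dtype=bool)
    g = np.where(mask, np.arctanh(np.clip(raw.estimate, -CORR_CLIP, CORR_CLIP)), 0.0)
    if weighted:
        with np.errstate(divide="ignore"):
            w = np.where(mask & (raw.se > 0), 1.0 / np.where(raw.se > 0, raw.se, 1.0) ** 2, 0.0)
        if mask.any():
            cap = np.quantile(w[mask], weight_cap_quantile)
            w = np.minimum(w, cap)
    else:
        w = np.ones((r, r))
    w = np.where(mask, w, 0.0)
    return g, mask, w


def diagonal_limit(g, mask, weights=None, band: int = 6):
    """Diagonal of the correlation surface by local extrapolation in lag.

    The true correlation surface equals 1 on the diagonal by definition,
    but a finite spline basis rounds the near-diagonal apex, so the
    coarse smoothed surface under-reads its own diagonal — and dividing
    by that value would corrupt the normalized matrix.  Instead, for
    each bin the observed Fisher-scale values within ``band`` cells of
    the diagonal are extrapolated to lag zero with a weighted quadratic
    in lag, clipped between the largest observed band value and
    atanh(0.9995).  Bins with too few observed lags inherit the median
    of the others.  Returns the per-bin diagonal on the correlation
    scale, in (0, 1).
    """
    g = np.asarray(g, float)
    r = g.shape[0]
    mask = np.asarray(mask, bool)
    w = np.ones_like(g) if weights is None else np.asarray(weights, float)
    out = np.full(r, np.nan)
    cap = np.arctanh(0.9995)
    for i in range(r):
        lags, ys, ws = [], [], []
        for L in range(1, band + 1):
            for j in (i - L, i + L):
                if 0 <= j < r and mask[i, j]:
                    lags.append(L)
                    ys.append(g[i, j])
                    ws.append(w[i, j])
        if len(set(lags)) >= 3:
            lags = np.asarray(lags, float)
            A = np.column_stack([np.ones_like(lags), lags, lags ** 2])
            sw = np.sqrt(np.asarray(ws))
            coef, *_ = np.linalg.lstsq(A * sw[:, None],
                                       np.asarray(ys) * sw, rcond=None)
            out[i] = min(max(coef[0], max(ys)), cap)
    missing = np.isnan(out)
    if missing.all():
        raise NormalizationError("no bin has enough near-diagonal coverage")
    if missing.any():
        out[missing] = np.median(out[~missing])
    return np.tanh(out)


def symmetric_pspline_fit(g, mask, weights=None, lam="auto",
                          grid: AgeGrid | None = None,
                          n_basis: int | None = None):
    """Symmetry-constrained P-spline fit of an incomplete Fisher surface.

    Fits on observed cells only and evaluates on the full grid, so
    uncovered regions are filled by the penalty's smooth extrapolation.
    Returns ``(G_hat, info)``.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise CannotFitError("all cells are masked; nothing to smooth")
    coords = grid.bins if grid is not None else np.arange(mask.shape[0])
    smoother = SymmetricSurfaceSmoother(coords, n_basis=n_basis)
    (res,) = smoother.fit([np.asarray(g, float)], mask, weights, lam=lam)
    return smoother.evaluate(res["coef"]), res


def finalize_correlation(G_hat, grid: AgeGrid, lower=None, upper=None,
                         fit_meta=None, measure: str = "", diag=None
                         ) -> SmoothCorrelationMatrix:
    """Back-transform and renormalize a smoothed Fisher surface.

    ``rho_hat = tanh(G_hat)`` is divided by the outer square root of the
    diagonal so the final matrix has an exact unit diagonal.  By default
    the smoothed surface's own diagonal is used; ``diag`` supplies a
    better-resolved estimate of the diagonal limit (see
    :func:`diagonal_limit`).  CI surfaces, when given (on the Fisher
    scale), are normalized by the same point-estimate diagonal.
    """
    rho_hat = np.tanh(np.asarray(G_hat, float))
    d = np.diag(rho_hat) if diag is None else np.asarray(diag, float)
    if np.any(d <= 0):
        bad = grid.bins[d <= 0]
        raise NormalizationError(
            f"non-positive smoothed diagonal at bins {bad[:10].tolist()}"
        )
    scale = np.sqrt(np.outer(d, d))

    def _normalize(surface_fisher):
        rho = np.tanh(np.asarray(surface_fisher, float)) / scale
        rho = (rho + rho.T) / 2.0
        off = ~np.eye(grid.n_bins, dtype=bool)
        n_clip = int(np.count_nonzero(np.abs(rho[off]) > CORR_CLIP))
        if n_clip:
            log.info("clipped %d off-diagonal entries to +/-%g", n_clip, CORR_CLIP)
        out = np.clip(rho, -CORR_CLIP, CORR_CLIP)
        np.fill_diagonal(out, 1.0)
        return out

    rho = _normalize(G_hat)
    if lower is not None and upper is not None:
        lo = _normalize(lower)
        up = _normalize(upper)
        unc = up - lo
        if np.any(unc < 0):
            log.warning("smoothed CI bounds cross on %d cells; flooring at 0",
                        int(np.count_nonzero(unc < 0)))
            unc = np.maximum(unc, 0.0)
        np.fill_diagonal(unc, 0.0)
    else:
        lo = up = rho
        unc = np.zeros_like(rho)
    return SmoothCorrelationMatrix(
        grid=grid, rho=rho, lower=lo, upper=up, uncertainty=unc,
        fit_meta=dict(fit_meta or {}), measure=measure,
    )


def smooth_surface(raw: RawCombinedSurface, lam="auto", weighted: bool = True,
                   n_basis: int | None = None, psd: bool = False,
                   psd_tol: float = 1e-8) -> SmoothCorrelationMatrix:
    """Full stage 2: point estimate plus CI bounds in one pass.

    With ``lam="auto"`` the smoothing parameter is chosen by spatially
    blocked cross-validation, which (unlike GCV) scores prediction into
    held-out regions — the actual job of stage 2, which must fill age
    pairs no study covers; ``lam="gcv"`` selects by plain GCV, and a
    float fixes the parameter.  The chosen lambda is shared by the CI
    bound surfaces, which reuse the point estimate's design, mask and
    weights, and the final matrix is renormalized with the
    lag-extrapolated diagonal limit (:func:`diagonal_limit`).
    """
    g, mask, w = to_fisher_surface(raw, weighted=weighted)
    if not mask.any():
        raise CannotFitError("raw surface has no usable off-diagonal cells")
    lo_g = np.where(mask, np.arctanh(np.clip(raw.lower, -CORR_CLIP, CORR_CLIP)), 0.0)
    up_g = np.where(mask, np.arctanh(np.clip(raw.upper, -CORR_CLIP, CORR_CLIP)), 0.0)
    smoother = SymmetricSurfaceSmoother(raw.grid.bins, n_basis=n_basis)
    lam_mode = lam
    if lam == "auto":
        lam = smoother.select_lambda_blocked(g, mask, w)
        if lam is None:  # grid too small to tile: fall back to GCV
            lam = "auto"
    elif lam == "gcv":
        lam = "auto"
    res = smoother.fit([g, lo_g, up_g], mask, w, lam=lam)
    G, Gl, Gu = (smoother.evaluate(r["coef"]) for r in res)
    diag = diagonal_limit(g, mask, w)
    fit_meta = {
        "lambda": res[0]["lambda"],
        "lambda_selection": ("blocked_cv" if lam_mode == "auto" else
                             "gcv" if lam_mode == "gcv" else "fixed"),
        "edf": res[0]["edf"],
        "n_basis": res[0]["n_basis"],
        "n_cells": res[0]["n_cells"],
        "weighted": bool(weighted),
    }
    out = finalize_correlation(G, raw.grid, lower=Gl, upper=Gu,
                               fit_meta=fit_meta, measure=raw.measure,
                               diag=diag)
    if psd:
        rho = nearest_psd_projection(out.rho, tol=psd_tol)
        out = SmoothCorrelationMatrix(
            grid=out.grid, rho=rho, lower=out.lower, upper=out.upper,
            uncertainty=out.uncertainty,
            fit_meta={**out.fit_meta, "psd_projected": True},
            measure=out.measure,
        )
    return out


def smooth_ci_surfaces(raw: RawCombinedSurface, lam="auto",
                       weighted: bool = True, n_basis: int | None = None):
    """Smoothed lower/upper confidence surfaces and their difference.

    Convenience wrapper around :func:`smooth_surface`; returns
    ``(lower, upper, uncertainty)``.
    """
    out = smooth_surface(raw, lam=lam, weighted=weighted, n_basis=n_basis)
    return out.lower, out.upper, out.uncertainty


def nearest_psd_projection(matrix, tol: float = 1e-8, max_iter: int = 200):
    """Nearest correlation matrix by alternating eigenvalue clipping.

    Optional post-processing (off by default): projects a symmetric
    unit-diagonal matrix to the positive-semidefinite cone.  Raises if
    the projection does not converge within ``max_iter`` sweeps.
    """
    a = np.asarray(matrix, float)
    if not np.array_equal(a, a.T):
        raise ValueError("input must be exactly symmetric")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("input must have a unit diagonal")
    if np.linalg.eigvalsh(a).min() >= -tol:
        return a.copy()
    out = corr_nearest(a, threshold=max(tol, 1e-15), n_fact=max_iter)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    min_eig = float(np.linalg.eigvalsh(out).min())
    if min_eig < -tol:
        raise RuntimeError(
            f"PSD projection did not converge: min eigenvalue {min_eig:g}"
        )
    delta = float(np.abs(out - a).max())
    log.info("PSD projection moved entries by at most %.3g", delta)
    return out
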