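"""Penalized B-spline (P-spline) machinery shared by both smoothing stages.

Univariate fits (study mean functions) and symmetric bivariate surface
fits (study covariance surfaces, stage-2 correlation surfaces) use cubic
B-spline bases with equally spaced knots and second-order difference
penalties on the coefficients, with the smoothing parameter chosen by
generalized cross-validation (GCV) over a log-spaced ladder.

The bivariate smoother enforces symmetry by half-parameterization: the
coefficient matrix is constrained to be symmetric by estimating only its
upper triangle, so the fitted surface is symmetric by construction
rather than by penalty.  Incomplete surfaces are handled by fitting to
the observed cells only; the second-order penalty extrapolates the fit
(linearly in each coordinate) into unobserved regions.

Normal equations are accumulated in chunks, so memory stays modest even
when hundreds of thousands of grid cells are observed, and GCV scores
are computed from the accumulated blocks without re-touching the data:
``RSS = y'Wy - 2 b'beta + beta'A beta`` with ``A = X'WX``, ``b = X'Wy``.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "bspline_basis",
    "difference_penalty",
    "default_lambda_ladder",
    "PSpline1D",
    "SymmetricSurfaceSmoother",
    "CannotFitError",
]

DEGREE = 3
#: Log-spaced smoothing-parameter ladder searched by GCV.
LAMBDA_LADDER = 10.0 ** np.arange(-2.0, 6.5, 0.5)
#: Relative ridge added to the penalized normal equations for conditioning.
RIDGE = 1e-10


class CannotFitError(RuntimeError):
    """No usable data cells (or degenerate design) for a penalized fit."""


def default_lambda_ladder():
    return LAMBDA_LADDER.copy()


def bspline_basis(x, xmin, xmax, n_basis, degree=DEGREE):
    """Dense cubic B-spline design matrix on an equally spaced knot grid.

    ``n_basis`` must be at least ``degree + 1``; the domain is split into
    ``n_basis - degree`` equal segments.
    """
    x = np.asarray(x, dtype=float)
    if n_basis < degree + 1:
        raise ValueError(f"n_basis must be >= {degree + 1}")
    if xmax <= xmin:
        raise ValueError("empty basis domain")
    nseg = n_basis - degree
    h = (xmax - xmin) / nseg
    inner = np.linspace(xmin, xmax, nseg + 1)  # exact endpoints
    knots = np.concatenate([
        xmin - h * np.arange(degree, 0, -1), inner,
        xmax + h * np.arange(1, degree + 1),
    ])
    return BSpline.design_matrix(np.clip(x, xmin, xmax), knots, degree).toarray(), knots


def difference_penalty(n_basis, order=2):
    """P = D'D for the difference matrix D of the given order."""
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def _gcv_path(A, rhs, yWy, n_obs, penalty, lambdas):
    """Solve the penalized normal equations along a lambda ladder.

    ``rhs`` may have several columns (surfaces sharing design and
    weights); GCV is evaluated per column and the per-column best lambda
    returned.  Returns (coefs, lambdas_chosen, edfs, gcv_table).
    """
    p = A.shape[0]
    ridge = RIDGE * (1.0 + np.trace(A) / p) * np.eye(p)
    rhs = np.atleast_2d(rhs.T).T  # (p, n_y)
    n_y = rhs.shape[1]
    gcv = np.full((len(lambdas), n_y), np.inf)
    edf_l = np.zeros(len(lambdas))
    betas = np.zeros((len(lambdas), p, n_y))
    for li, lam in enumerate(lambdas):
        M = A + lam * penalty + ridge
        try:
            c = cho_factor(M, lower=True)
        except np.linalg.LinAlgError:
            continue
        beta = cho_solve(c, rhs)
        betas[li] = beta
        edf = float(np.trace(cho_solve(c, A)))
        edf_l[li] = edf
        rss = yWy - 2.0 * np.einsum("pj,pj->j", rhs, beta) \
            + np.einsum("pj,pq,qj->j", beta, A, beta)
        rss = np.maximum(rss, 0.0)
        denom = max(n_obs - edf, 1e-8) ** 2
        gcv[li] = n_obs * rss / denom
    if not np.isfinite(gcv).any():
        raise CannotFitError("penalized normal equations are singular at all lambdas")
    best = np.argmin(gcv, axis=0)
    coefs = np.stack([betas[best[j], :, j] for j in range(n_y)], axis=1)
    return coefs, lambdas[best], edf_l[best], gcv


class PSpline1D:
    """Univariate penalized B-spline regression with GCV-selected lambda."""

    def __init__(self, n_basis=35, degree=DEGREE, penalty_order=2):
        self.n_basis = n_basis
        self.degree = degree
        self.penalty_order = penalty_order
        self.coef_ = None

    def fit(self, x, y, weights=None, lam="auto"):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size == 0:
            raise CannotFitError("no data")
        self.xmin_, self.xmax_ = float(x.min()), float(x.max())
        if self.xmax_ <= self.xmin_:
            raise CannotFitError("all observations at a single age")
        m = int(min(self.n_basis, max(self.degree + 1, x.size)))
        B, self.knots_ = bspline_basis(x, self.xmin_, self.xmax_, m, self.degree)
        w = np.ones_like(y) if weights is None else np.asarray(weights, float)
        A = (B * w[:, None]).T @ B
        b = B.T @ (w * y)
        yWy = float(w @ (y * y))
        P = difference_penalty(m, self.penalty_order)
        lambdas = LAMBDA_LADDER if lam == "auto" else np.array([float(lam)])
        coefs, lam_best, edf, _ = _gcv_path(A, b[:, None], np.array([yWy]),
                                            x.size, P, lambdas)
        self.coef_ = coefs[:, 0]
        self.lambda_ = float(lam_best[0])
        self.edf_ = float(edf[0])
        self.n_basis_ = m
        return self

    def __call__(self, x):
        if self.coef_ is None:
            raise RuntimeError("fit before evaluating")
        B, _ = bspline_basis(np.asarray(x, float), self.xmin_, self.xmax_,
                             self.n_basis_, self.degree)
        return B @ self.coef_


class SymmetricSurfaceSmoother:
    """Symmetric bivariate P-spline smoother over a square age domain.

    Fits ``g(s, t)`` using a tensor-product cubic B-spline basis with
    the coefficient matrix constrained symmetric (half-
    parameterization), second-order difference penalties along both
    axes, and weighted least squares.  Data can be grid cells
    (:meth:`fit`) or arbitrary symmetric point pairs
    (:meth:`fit_points`); either way the fit is evaluated on any set of
    coordinates afterwards, so fitting resolution and output grid are
    independent.
    """

    CHUNK = 2048

    def __init__(self, coords, n_basis=None, degree=DEGREE, penalty_order=2,
                 domain=None):
        self.coords = np.asarray(coords, dtype=float)
        r = self.coords.size
        if n_basis is None:
            n_basis = max(8, min(40, r // 5))
        self.m = int(min(max(degree + 1, n_basis), max(degree + 1, r)))
        self.degree = degree
        lo, hi = domain if domain is not None else (self.coords.min(),
                                                    self.coords.max())
        self.domain = (float(lo), float(hi))
        self.B, self.knots = bspline_basis(self.coords, *self.domain,
                                           self.m, degree)
        m = self.m
        # Half-parameterization: theta_full[p, q] = theta_half[tri(min, max)]
        iu, ju = np.triu_indices(m)
        half_index = np.zeros((m, m), dtype=np.int64)
        half_index[iu, ju] = np.arange(iu.size)
        half_index = np.maximum(half_index, half_index.T)
        rows = np.arange(m * m)
        self.n_half = iu.size
        self.S = sparse.csr_matrix(
            (np.ones(m * m), (rows, half_index.ravel())),
            shape=(m * m, self.n_half),
        )
        P1 = difference_penalty(m, penalty_order)
        Pf = sparse.kron(sparse.eye(m), P1) + sparse.kron(P1, sparse.eye(m))
        self.penalty = np.asarray((self.S.T @ Pf @ self.S).todense())

    def _accumulate(self, Bs, Bt, ys, w):
        """Chunked normal equations from design row blocks."""
        n_obs = Bs.shape[0]
        A = np.zeros((self.n_half, self.n_half))
        b = np.zeros((self.n_half, ys.shape[1]))
        yWy = (w[:, None] * ys * ys).sum(axis=0)
        for s in range(0, n_obs, self.CHUNK):
            sl = slice(s, s + self.CHUNK)
            Xf = Bs[sl][:, :, None] * Bt[sl][:, None, :]
            Xh = Xf.reshape(Xf.shape[0], -1) @ self.S
            Xw = Xh * w[sl, None]
            A += Xw.T @ Xh
            b += Xw.T @ ys[sl]
        return A, b, yWy, n_obs

    def _normal_equations(self, y_list, mask, weights):
        ii, jj = np.nonzero(mask)
        if ii.size == 0:
            raise CannotFitError("all surface cells are masked")
        w = weights[ii, jj]
        ys = np.stack([y[ii, jj] for y in y_list], axis=1)  # (n_obs, n_y)
        return self._accumulate(self.B[ii], self.B[jj], ys, w)

    def fit(self, y_list, mask, weights=None, lam="auto"):
        """Fit one or more surfaces sharing the same mask and weights.

        Parameters
        ----------
        y_list : sequence of (r, r) arrays
            Surfaces to smooth (e.g. point estimate plus CI bounds).
        mask : (r, r) bool array
            True where a cell is observed.
        weights : (r, r) array, optional
            Non-negative cell weights; ones by default.
        lam : "auto" or float
            GCV over the ladder, or a fixed smoothing parameter.

        Returns a list of dicts with ``coef`` (half-parameters),
        ``lambda``, ``edf`` per surface.
        """
        mask = np.asarray(mask, bool)
        if weights is None:
            weights = np.ones(mask.shape)
        A, b, yWy, n_obs = self._normal_equations(y_list, mask, weights)
        lambdas = LAMBDA_LADDER if lam == "auto" else np.array([float(lam)])
        coefs, lam_best, edf, _ = _gcv_path(A, b, yWy, n_obs, self.penalty, lambdas)
        return [
            {"coef": coefs[:, j], "lambda": float(lam_best[j]),
             "edf": float(edf[j]), "n_basis": self.m, "n_cells": int(n_obs)}
            for j in range(coefs.shape[1])
        ]

    def select_lambda_blocked(self, y, mask, weights=None, lambdas=None,
                              n_blocks=12):
        """Smoothing parameter by spatially blocked cross-validation.

        The grid is tiled into ``n_blocks x n_blocks`` blocks; each fold
        holds out one block together with its mirror (symmetric cells
        carry the same information, so leaving the mirror in would leak).
        Predicting a held-out block from the rest mimics the real task
        of filling unobserved regions, so this criterion — unlike GCV,
        which only scores interpolation on observed cells — is sensitive
        to extrapolation quality.  Returns the winning lambda, or None
        when fewer than two folds contain data (caller falls back to GCV).
        """
        mask = np.asarray(mask, bool)
        r = mask.shape[0]
        if weights is None:
            weights = np.ones(mask.shape)
        if lambdas is None:
            lambdas = LAMBDA_LADDER
        ii, jj = np.nonzero(mask)
        if ii.size == 0:
            raise CannotFitError("all surface cells are masked")
        size = max(2, int(np.ceil(r / n_blocks)))
        bi, bj = ii // size, jj // size
        lo, hi = np.minimum(bi, bj), np.maximum(bi, bj)
        fold_key = lo * n_blocks + hi
        folds = np.unique(fold_key)
        if folds.size < 2:
            return None
        w = weights[ii, jj]
        yv = np.asarray(y, float)[ii, jj][:, None]
        blocks = {}
        for f in folds:
            sel = fold_key == f
            blocks[f] = self._accumulate(self.B[ii[sel]], self.B[jj[sel]],
                                         yv[sel], w[sel])
        A = sum(b[0] for b in blocks.values())
        rhs = sum(b[1] for b in blocks.values())
        p = A.shape[0]
        ridge = RIDGE * (1.0 + np.trace(A) / p) * np.eye(p)
        scores = np.full(len(lambdas), np.inf)
        for li, lam in enumerate(lambdas):
            score = 0.0
            ok = True
            for f in folds:
                A_f, b_f, yWy_f, _ = blocks[f]
                M = A - A_f + lam * self.penalty + ridge
                try:
                    beta = cho_solve(cho_factor(M, lower=True), rhs - b_f)
                except np.linalg.LinAlgError:
                    ok = False
                    break
                score += float(yWy_f[0] - 2.0 * (beta[:, 0] @ b_f[:, 0])
                               + beta[:, 0] @ A_f @ beta[:, 0])
            if ok:
                scores[li] = score
        if not np.isfinite(scores).any():
            return None
        # parsimony rule: the CV curve is typically flat near its minimum,
        # so take the largest (smoothest) lambda within 5% of the best
        # score rather than the literal argmin
        best = np.nanmin(scores)
        within = np.nonzero(scores <= 1.05 * best)[0]
        return float(lambdas[within[-1]])

    def fit_points(self, s, t, y, weights=None, lam="auto"):
        """Fit one surface to arbitrary symmetric point data.

        ``s``, ``t`` are coordinates inside the domain and ``y`` the
        observed values; because the coefficient matrix is symmetric,
        rows for (s, t) and (t, s) are identical and ordered pairs can
        be fed as they come.  Returns a fit dict as in :meth:`fit`.
        """
        s = np.asarray(s, float)
        t = np.asarray(t, float)
        y = np.asarray(y, float)
        if s.size == 0:
            raise CannotFitError("no point data")
        w = np.ones(s.size) if weights is None else np.asarray(weights, float)
        Bs, _ = bspline_basis(s, *self.domain, self.m, self.degree)
        Bt, _ = bspline_basis(t, *self.domain, self.m, self.degree)
        A, b, yWy, n_obs = self._accumulate(Bs, Bt, y[:, None], w)
        lambdas = LAMBDA_LADDER if lam == "auto" else np.array([float(lam)])
        coefs, lam_best, edf, _ = _gcv_path(A, b, yWy, n_obs, self.penalty, lambdas)
        return {"coef": coefs[:, 0], "lambda": float(lam_best[0]),
                "edf": float(edf[0]), "n_basis": self.m, "n_cells": int(n_obs)}

    def evaluate(self, coef_half, coords=None):
        """Evaluate a fitted surface on a coordinate grid; exactly symmetric."""
        theta = np.asarray(self.S @ coef_half).reshape(self.m, self.m)
        if coords is None:
            B = self.B
        else:
            B, _ = bspline_basis(np.asarray(coords, float), *self.domain,
                                 self.m, self.degree)
        G = B @ theta @ B.T
        return (G + G.T) / 2.0

    def effective_df(self, mask, weights=None, lam=1.0):
        """Effective degrees of freedom of the smoother at a fixed lambda."""
        mask = np.asarray(mask, bool)
        if weights is None:
            weights = np.ones(mask.shape)
        A, _, _, _ = self._normal_equations([np.zeros(mask.shape)], mask, weights)
        ridge = RIDGE * (1.0 + np.trace(A) / A.shape[0]) * np.eye(A.shape[0])
        c = cho_factor(A + lam * self.penalty + ridge, lower=True)
        return float(np.trace(cho_solve(c, A)))
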