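"""Stage-2 surface smoothing, renormalization and CI surfaces."""

import numpy as np
import pytest

import growthcorr as gc
from growthcorr.smooth import NormalizationError, diagonal_limit


def synthetic_raw(grid, truth_rho, se, mask=None, count=None):
    """Assemble a RawCombinedSurface with given estimate and SE layers."""
    r = grid.n_bins
    est = np.clip(truth_rho, -0.999, 0.999)
    se = np.broadcast_to(se, (r, r)).astype(float)
    if mask is None:
        mask = np.ones((r, r), bool)
    if count is None:
        count = mask.astype(np.int64)
    m = np.arctanh(est)
    lower = np.tanh(m - 1.96 * se)
    upper = np.tanh(m + 1.96 * se)
    z = np.zeros((r, r))
    return gc.RawCombinedSurface(
        grid=grid, estimate=np.where(mask, est, 0.0),
        fisher_mean=np.where(mask, m, 0.0), tau2=z,
        se=np.where(mask, se, 0.0), lower=np.where(mask, lower, 0.0),
        upper=np.where(mask, upper, 0.0), count=np.where(mask, count, 0),
        mask=mask)


def exp_truth(grid, phi_bins):
    lag = np.abs(np.subtract.outer(np.arange(grid.n_bins),
                                   np.arange(grid.n_bins))).astype(float)
    rho = np.exp(-lag / phi_bins)
    np.fill_diagonal(rho, 1.0)
    return rho


GRID = gc.AgeGrid(0, 273, 7)  # 40 bins


class TestToFisherSurface:
    def test_diagonal_always_masked(self):
        raw = synthetic_raw(GRID, exp_truth(GRID, 8.0), 0.05)
        g, mask, w = gc.to_fisher_surface(raw)
        assert not mask.diagonal().any()

    def test_zero_correlation_maps_to_zero(self):
        rho = exp_truth(GRID, 8.0)
        rho[0, 30] = rho[30, 0] = 0.0
        raw = synthetic_raw(GRID, rho, 0.05)
        g, mask, w = gc.to_fisher_surface(raw)
        assert g[0, 30] == 0.0 and mask[0, 30]

    def test_uncovered_cells_have_zero_weight(self):
        mask = np.ones((40, 40), bool)
        mask[:5, 30:] = False
        mask[30:, :5] = False
        raw = synthetic_raw(GRID, exp_truth(GRID, 8.0), 0.05, mask=mask)
        g, m, w = gc.to_fisher_surface(raw)
        assert not m[0, 35] and w[0, 35] == 0.0

    def test_weights_capped_at_quantile(self):
        se = np.full((40, 40), 0.1)
        se[3, 4] = se[4, 3] = 1e-6   # absurdly precise cell
        raw = synthetic_raw(GRID, exp_truth(GRID, 8.0), se)
        _, m, w = gc.to_fisher_surface(raw)
        assert w[3, 4] <= np.quantile(w[m], 0.95) * (1 + 1e-12)


class TestFinalize:
    def test_hand_worked_normalization(self):
        grid2 = gc.AgeGrid(0, 7, 7)
        G = np.arctanh(np.array([[0.9, 0.6], [0.6, 0.8]]))
        out = gc.finalize_correlation(G, grid2)
        assert out.rho[0, 1] == pytest.approx(0.6 / np.sqrt(0.72), abs=1e-9)
        assert out.rho[0, 1] == pytest.approx(0.70711, abs=1e-5)

    def test_normalization_identity_when_diagonal_is_one(self):
        grid2 = gc.AgeGrid(0, 14, 7)
        rho = np.array([[0.9999999, 0.5, 0.2],
                        [0.5, 0.9999999, 0.4],
                        [0.2, 0.4, 0.9999999]])
        out = gc.finalize_correlation(np.arctanh(rho), grid2)
        assert np.allclose(out.rho[0, 1], 0.5, atol=1e-5)

    def test_output_invariants(self):
        G = np.arctanh(np.clip(exp_truth(GRID, 8.0), None, 0.999))
        out = gc.finalize_correlation(G, GRID)
        assert np.array_equal(out.rho, out.rho.T)
        assert np.all(np.diag(out.rho) == 1.0)
        off = ~np.eye(40, dtype=bool)
        assert np.all(np.abs(out.rho[off]) < 1.0)

    def test_non_positive_diagonal_raises(self):
        G = np.arctanh(np.clip(exp_truth(GRID, 8.0), None, 0.999))
        G[0, 0] = -0.5
        with pytest.raises(NormalizationError, match="bins"):
            gc.finalize_correlation(G, GRID)


class TestDiagonalLimit:
    def test_recovers_unit_diagonal_from_decay(self):
        raw = synthetic_raw(GRID, exp_truth(GRID, 8.0), 0.02)
        g, mask, w = gc.to_fisher_surface(raw)
        d = diagonal_limit(g, mask, w)
        assert np.all(d > 0.9) and np.all(d < 1.0)


class TestSmoothSurface:
    def test_completes_and_validates(self):
        mask = np.ones((40, 40), bool)
        mask[:8, 28:] = False
        mask[28:, :8] = False
        raw = synthetic_raw(GRID, exp_truth(GRID, 8.0), 0.05, mask=mask)
        out = gc.smooth_surface(raw)
        assert out.rho.shape == (40, 40)
        assert np.isfinite(out.rho).all()          # complete: filled corners
        assert np.all(out.uncertainty >= 0)

    def test_filled_corner_near_truth(self):
        rho = exp_truth(GRID, 8.0)
        mask = np.ones((40, 40), bool)
        mask[:8, 28:] = False
        mask[28:, :8] = False
        raw = synthetic_raw(GRID, rho, 0.05, mask=mask)
        out = gc.smooth_surface(raw)
        corner = np.zeros((40, 40), bool)
        corner[:8, 28:] = True
        assert np.abs(out.rho - rho)[corner].mean() < 0.15

    def test_degenerate_equal_bounds_give_zero_uncertainty(self):
        raw = synthetic_raw(GRID, exp_truth(GRID, 8.0), 1e-12)
        lower, upper, unc = gc.smooth_ci_surfaces(raw)
        assert np.abs(unc).max() < 1e-6

    def test_uncertainty_larger_where_coverage_is_thin(self):
        # wide CIs in one corner block, tight in the dense core
        se = np.full((40, 40), 0.02)
        se[25:, 25:] = 0.4
        se = np.maximum(se, se.T)
        raw = synthetic_raw(GRID, exp_truth(GRID, 8.0), se)
        _, _, unc = gc.smooth_ci_surfaces(raw)
        sparse = unc[30:, 30:][~np.eye(10, dtype=bool)].mean()
        core = unc[5:15, 5:15][~np.eye(10, dtype=bool)].mean()
        assert sparse > 2 * core

    def test_bounds_ordering_preserved_on_separated_toy(self):
        raw = synthetic_raw(GRID, exp_truth(GRID, 12.0), 0.1)  # gap ~0.2 on rho
        lower, upper, unc = gc.smooth_ci_surfaces(raw)
        off = ~np.eye(40, dtype=bool)
        assert np.all(upper[off] >= lower[off])

    def test_all_masked_raises(self):
        raw = synthetic_raw(GRID, exp_truth(GRID, 8.0), 0.05,
                            mask=np.zeros((40, 40), bool))
        with pytest.raises(Exception):
            gc.smooth_surface(raw)


class TestNearestPSD:
    def test_psd_input_returned_unchanged(self):
        a = exp_truth(GRID, 8.0)
        out = gc.nearest_psd_projection(a)
        assert np.allclose(out, a, atol=1e-12)

    def test_indefinite_matrix_projected(self):
        a = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        assert np.linalg.eigvalsh(a).min() < 0
        out = gc.nearest_psd_projection(a, tol=1e-7)
        assert np.linalg.eigvalsh(out).min() >= -1e-7
        assert np.all(np.diag(out) == 1.0)

    def test_requires_unit_diagonal(self):
        with pytest.raises(ValueError):
            gc.nearest_psd_projection(np.array([[2.0, 0.1], [0.1, 2.0]]))
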