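"""Fisher transform and elementwise random-effects pooling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import growthcorr as gc
from conftest import dl_brute_force


class TestFisher:
    def test_known_values(self):
        assert gc.fisher_z(0.0) == 0.0
        assert gc.fisher_z(0.66) == pytest.approx(0.79281, abs=5e-6)

    def test_inverse_identity(self):
        for rho in (-0.95, -0.3, 0.0, 0.5, 0.9):
            assert gc.inverse_fisher(gc.fisher_z(rho)) == pytest.approx(rho, abs=1e-12)

    def test_odd_and_increasing(self):
        x = np.linspace(-0.99, 0.99, 101)
        z = gc.fisher_z(x)
        assert np.allclose(z, -gc.fisher_z(-x))
        assert (np.diff(z) > 0).all()

    def test_domain_error(self):
        with pytest.raises(ValueError):
            gc.fisher_z(1.0)

    @pytest.mark.parametrize("n,expected", [(103, 0.01), (4, 1.0)])
    def test_variance_large_sample(self, n, expected):
        assert gc.fisher_variance(n) == pytest.approx(expected)

    def test_variance_undefined_below_four(self):
        assert np.isnan(gc.fisher_variance(3))


class TestEntryMeta:
    def test_single_study_passthrough(self):
        m, se, tau2 = gc.entry_meta([0.5], [0.04])
        assert (m, se, tau2) == (0.5, pytest.approx(0.2), 0.0)

    def test_hand_worked_dersimonian_laird(self):
        m, se, tau2 = gc.entry_meta([0.4, 0.6], [0.01, 0.01])
        assert tau2 == pytest.approx(0.01)
        assert m == pytest.approx(0.5)
        m, se, tau2 = gc.entry_meta([0.0, 1.0], [0.01, 0.01])
        assert tau2 == pytest.approx(0.49)
        assert m == pytest.approx(0.5)

    def test_empty_input_is_missing(self):
        assert all(np.isnan(v) for v in gc.entry_meta([], []))

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.001, 2.0)),
                    min_size=1, max_size=8))
    def test_matches_brute_force(self, pairs):
        f = [p[0] for p in pairs]
        v = [p[1] for p in pairs]
        got = gc.entry_meta(f, v)
        want = dl_brute_force(f, v)
        assert got == pytest.approx(want, abs=1e-10)


def toy_study(study_id, grid, first, last, rho, n_eff=103, n_children=200):
    """Study covering bins [first, last] with stationary correlation rho."""
    bins = np.arange(first, last + 1)
    s = bins.size
    lag = np.abs(np.subtract.outer(bins, bins))
    corr = rho ** lag.astype(float)
    np.fill_diagonal(corr, 1.0)
    return gc.StudyCorrelation(
        study_id, grid, bins, corr,
        np.full((s, s), n_eff, dtype=np.int64),
        np.ones((s, s), bool), n_children)


class TestCombine:
    grid = gc.AgeGrid(0, 140, 7)  # 21 bins

    def test_single_study_entry_passthrough(self):
        st1 = toy_study("a", self.grid, 0, 10, 0.8)
        raw = gc.combine_matrices(gc.align_studies([st1], self.grid))
        loc = np.ix_(st1.bins, st1.bins)
        off = ~np.eye(11, dtype=bool)
        assert np.allclose(raw.estimate[loc][off], st1.corr[off], atol=1e-9)
        assert raw.count[0, 0] == 1

    def test_uncovered_entries_flagged_for_stage_two(self):
        st1 = toy_study("a", self.grid, 0, 10, 0.8)
        raw = gc.combine_matrices(gc.align_studies([st1], self.grid))
        assert raw.count[15, 15] == 0 and not raw.mask[15, 15]
        assert raw.count[0, 15] == 0   # young x old never co-observed

    def test_two_studies_match_brute_force(self):
        st1 = toy_study("a", self.grid, 0, 12, 0.8, n_eff=103)
        st2 = toy_study("b", self.grid, 5, 18, 0.6, n_eff=53)
        raw = gc.combine_matrices(gc.align_studies([st1, st2], self.grid))
        i, j = 6, 9  # covered by both
        f = [np.arctanh(st1.corr[6, 9]), np.arctanh(st2.corr[1, 4])]
        v = [1.0 / 100.0, 1.0 / 50.0]
        m, se, tau2 = dl_brute_force(f, v)
        assert raw.estimate[i, j] == pytest.approx(np.tanh(m), abs=1e-12)
        assert raw.se[i, j] == pytest.approx(se, abs=1e-12)
        assert raw.tau2[i, j] == pytest.approx(tau2, abs=1e-12)
        assert raw.count[i, j] == 2

    def test_weight_monotonicity(self):
        # inflating study b's variance must pull the pooled value
        # toward study a's correlation
        st1 = toy_study("a", self.grid, 0, 10, 0.8, n_eff=103)
        pooled = []
        for n_eff_b in (103, 13, 5):
            st2 = toy_study("b", self.grid, 0, 10, 0.3, n_eff=n_eff_b)
            raw = gc.combine_matrices(gc.align_studies([st1, st2], self.grid))
            pooled.append(raw.estimate[2, 3])
        assert pooled[0] < pooled[1] < pooled[2] < st1.corr[2, 3]

    def test_identical_studies_give_common_value_and_zero_tau2(self):
        studies = [toy_study(f"s{k}", self.grid, 0, 10, 0.7) for k in range(4)]
        raw = gc.combine_matrices(gc.align_studies(studies, self.grid))
        off = ~np.eye(21, dtype=bool)
        covered = raw.mask & off
        loc = np.ix_(studies[0].bins, studies[0].bins)
        assert np.allclose(raw.estimate[loc][~np.eye(11, dtype=bool)],
                           studies[0].corr[~np.eye(11, dtype=bool)], atol=1e-9)
        assert np.allclose(raw.tau2[covered], 0.0, atol=1e-12)

    def test_outputs_exactly_symmetric(self):
        st1 = toy_study("a", self.grid, 0, 12, 0.8)
        st2 = toy_study("b", self.grid, 5, 18, 0.6, n_eff=23)
        raw = gc.combine_matrices(gc.align_studies([st1, st2], self.grid))
        for layer in (raw.estimate, raw.se, raw.tau2, raw.lower, raw.upper,
                      raw.count, raw.mask):
            assert np.array_equal(layer, layer.T)

    def test_ci_brackets_estimate(self):
        st1 = toy_study("a", self.grid, 0, 12, 0.8)
        st2 = toy_study("b", self.grid, 5, 18, 0.6, n_eff=23)
        raw = gc.combine_matrices(gc.align_studies([st1, st2], self.grid))
        m = raw.mask
        assert np.all(raw.lower[m] <= raw.estimate[m])
        assert np.all(raw.estimate[m] <= raw.upper[m])

    def test_count_layer_reproduces_coverage_pattern(self):
        st1 = toy_study("a", self.grid, 0, 10, 0.8)
        st2 = toy_study("b", self.grid, 5, 18, 0.6)
        raw = gc.combine_matrices(gc.align_studies([st1, st2], self.grid))
        expected = np.zeros((21, 21), dtype=int)
        expected[np.ix_(range(0, 11), range(0, 11))] += 1
        expected[np.ix_(range(5, 19), range(5, 19))] += 1
        assert np.array_equal(raw.count, expected)

    def test_low_n_eff_entries_excluded(self):
        st1 = toy_study("a", self.grid, 0, 10, 0.8, n_eff=3)
        raw = gc.combine_matrices(gc.align_studies([st1], self.grid))
        assert not raw.mask.any()

    def test_shared_tau2_mode(self):
        st1 = toy_study("a", self.grid, 0, 12, 0.8)
        st2 = toy_study("b", self.grid, 0, 12, 0.5)
        raw = gc.combine_matrices(gc.align_studies([st1, st2], self.grid),
                                  shared_tau2=True)
        covered = raw.mask & (raw.count >= 2)
        vals = raw.tau2[covered]
        assert np.allclose(vals, vals.flat[0])
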