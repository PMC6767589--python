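"""Single-study covariance estimation: mean removal, cross-products, recovery."""

import numpy as np
import pandas as pd
import pytest

import growthcorr as gc
from growthcorr.studycov import InsufficientDataError


class ZeroMean:
    """Stand-in mean function returning 0 (records are already centred)."""

    def __call__(self, ages):
        return np.zeros_like(np.asarray(ages, float))


def record_set(rows):
    df = pd.DataFrame(rows, columns=["child", "age_days", "z"])
    df["measure"] = "HAZ"
    return gc.GrowthRecordSet("toy", df)


class TestMeanFunction:
    def test_recovers_linear_trend(self):
        rng = np.random.default_rng(0)
        ages = rng.integers(0, 500, 200)
        rows = [(f"c{i}", a, 0.001 * a) for i, a in enumerate(ages)]
        mu = gc.fit_mean_function(record_set(rows))
        x = np.linspace(ages.min(), ages.max(), 50)
        assert np.abs(mu(x) - 0.001 * x).max() < 1e-3

    def test_residual_mean_near_zero(self, dense_study):
        records, _ = dense_study
        mu = gc.fit_mean_function(records)
        resid = records.records["z"].to_numpy() - mu(records.records["age_days"].to_numpy())
        assert abs(resid.mean()) < 1e-6

    def test_too_few_observations_raises(self):
        rows = [(f"c{i}", 10 * i, 0.0) for i in range(10)]
        with pytest.raises(InsufficientDataError):
            gc.fit_mean_function(record_set(rows))

    def test_single_age_raises(self):
        rows = [(f"c{i}", 100, 0.1) for i in range(30)]
        with pytest.raises(InsufficientDataError):
            gc.fit_mean_function(record_set(rows))


class TestCrossProducts:
    def test_ordered_pair_counts(self):
        rows = [("a", 10, 1.0), ("a", 20, 2.0), ("a", 30, 3.0)]
        pairs, var_stream = gc.empirical_cross_products(record_set(rows), ZeroMean())
        assert len(pairs) == 6          # 3 x 2 ordered distinct-visit pairs
        assert len(var_stream) == 3     # one same-visit square per record

    def test_single_visit_child_contributes_nothing(self):
        rows = [("a", 10, 1.0)]
        pairs, _ = gc.empirical_cross_products(record_set(rows), ZeroMean())
        assert len(pairs) == 0

    def test_two_child_toy_products(self):
        # residuals child1: (-1, +1), child2: (+1, +1)
        rows = [("c1", 10, -1.0), ("c1", 20, 1.0),
                ("c2", 10, 1.0), ("c2", 20, 1.0)]
        pairs, _ = gc.empirical_cross_products(record_set(rows), ZeroMean())
        assert sorted(pairs["product"].tolist()) == [-1.0, -1.0, 1.0, 1.0]

    def test_same_visit_squares_kept_separate(self):
        rows = [("a", 10, 2.0), ("a", 20, 3.0)]
        pairs, var_stream = gc.empirical_cross_products(record_set(rows), ZeroMean())
        assert set(pairs["product"]) == {6.0}
        assert sorted(var_stream["square"]) == [4.0, 9.0]


class TestStudyCorrelation:
    def test_structural_invariants(self, dense_study_corr):
        sc, _ = dense_study_corr
        assert np.array_equal(sc.corr, sc.corr.T)
        assert np.all(np.diag(sc.corr) == 1.0)
        assert np.all(np.abs(sc.corr) <= 1.0)
        assert np.all(sc.n_eff <= sc.n_children)

    def test_recovers_exponential_truth(self, dense_study_corr):
        # truth exp(-|s-t|/150 days), 500 children: mean absolute error
        # below 0.07 wherever at least 30 children inform the entry
        sc, truth = dense_study_corr
        loc = sc.bins - truth.grid.first_bin
        T = truth.rho[np.ix_(loc, loc)]
        m = sc.mask & (sc.n_eff >= 30) & ~np.eye(len(sc.bins), dtype=bool)
        assert m.sum() > 500
        assert np.abs(sc.corr - T)[m].mean() < 0.07

    def test_measurement_error_nugget_not_attenuating(self):
        # adding visit-level noise var 0.3 would attenuate a naive
        # correlation by 1/1.3; excluding same-visit products keeps the
        # estimate on the process scale
        design = gc.StudyDesign("nug", 500, 1, 300, 20, 25, 30,
                                error_sd=np.sqrt(0.3))
        cfg = gc.SimulationConfig(studies=(design,),
                                  truth=gc.ExponentialTruth(150.0), seed=0)
        records, truth = gc.simulate_multistudy(cfg)
        sc = gc.study_correlation(records[0])
        loc = sc.bins - truth.grid.first_bin
        T = truth.rho[np.ix_(loc, loc)]
        m = sc.mask & (sc.n_eff >= 30) & ~np.eye(len(sc.bins), dtype=bool)
        ratio = (sc.corr[m] / T[m]).mean()
        assert np.abs(sc.corr - T)[m].mean() < 0.07
        assert ratio > 1.0 / 1.15          # nowhere near the 1/1.3 attenuation

    def test_coverage_restricted_to_observed_window(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(60):
            for a in rng.integers(150, 451, 6):
                rows.append((f"c{i}", int(a), rng.normal()))
        df = pd.DataFrame(rows, columns=["child", "age_days", "z"])
        df = df.drop_duplicates(["child", "age_days"])
        df["measure"] = "HAZ"
        sc = gc.study_correlation(gc.GrowthRecordSet("win", df), n_min=3)
        assert sc.bins[0] >= round(150 / 7) and sc.bins[-1] <= round(450 / 7)

    def test_entries_below_n_min_masked(self, dense_study_corr):
        sc, _ = dense_study_corr
        assert not sc.mask[sc.n_eff < 10].any()

    def test_records_outside_grid_dropped(self, caplog):
        rng = np.random.default_rng(6)
        rows = [(f"c{i}", int(a), rng.normal())
                for i in range(40) for a in rng.integers(1, 400, 5)]
        rows.append(("c0", 9000, 0.1))  # beyond the 6570-day grid
        df = pd.DataFrame(rows, columns=["child", "age_days", "z"])
        df = df.drop_duplicates(["child", "age_days"])
        df["measure"] = "HAZ"
        with caplog.at_level("WARNING", logger="growthcorr"):
            sc = gc.study_correlation(gc.GrowthRecordSet("rng", df), n_min=3)
        assert sc.bins[-1] <= 940
        assert any("outside the grid" in r.message for r in caplog.records)
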