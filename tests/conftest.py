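"""Shared fixtures: small synthetic studies and grids, generated at test time."""

import logging

import numpy as np
import pytest

import growthcorr as gc

logging.getLogger("growthcorr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def weekly_grid():
    return gc.AgeGrid()


@pytest.fixture(scope="session")
def dense_study():
    """One dense cohort (500 children, 20-30 visits over 300 days) with
    exponential truth phi = 150 days and measurement noise sd 0.2."""
    design = gc.StudyDesign("dense", 500, 1, 300, 20, 25, 30, error_sd=0.2)
    cfg = gc.SimulationConfig(studies=(design,),
                              truth=gc.ExponentialTruth(150.0), seed=0)
    records, truth = gc.simulate_multistudy(cfg)
    return records[0], truth


@pytest.fixture(scope="session")
def dense_study_corr(dense_study):
    records, truth = dense_study
    return gc.study_correlation(records), truth


@pytest.fixture(scope="session")
def three_study_records():
    """Three small overlapping studies on a narrow grid for pipeline tests."""
    studies = tuple(
        gc.StudyDesign(f"s{i}", 120, 1 + 250 * i, 900 + 250 * i, 4, 8, 12, 0.2)
        for i in range(3)
    )
    cfg = gc.SimulationConfig(studies=studies,
                              truth=gc.ExponentialTruth(150.0), seed=7)
    records, truth = gc.simulate_multistudy(cfg, gc.AgeGrid(0, 1980, 20))
    return records, truth


def dl_brute_force(values, variances):
    """Independent scalar reimplementation of the DerSimonian-Laird pool."""
    f = list(map(float, values))
    v = list(map(float, variances))
    if len(f) == 1:
        return f[0], v[0] ** 0.5, 0.0
    w0 = [1.0 / x for x in v]
    sw0 = sum(w0)
    fbar = sum(wi * fi for wi, fi in zip(w0, f)) / sw0
    Q = sum(wi * (fi - fbar) ** 2 for wi, fi in zip(w0, f))
    C = sw0 - sum(wi * wi for wi in w0) / sw0
    tau2 = max(0.0, (Q - (len(f) - 1)) / C)
    w = [1.0 / (vi + tau2) for vi in v]
    sw = sum(w)
    m = sum(wi * fi for wi, fi in zip(w, f)) / sw
    return m, sw ** -0.5, tau2
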