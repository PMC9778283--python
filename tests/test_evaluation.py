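"""Deviation statistics, lead selection, agreement and regression."""

import numpy as np
import pytest

from ecgdelin.evaluation import (DeviationReport, REPORTED_POINTS,
                                 bland_altman, deviations_ms, mae_of_means,
                                 regression_fit, select_lead)


def test_zero_deviation_for_perfect_prediction():
    truth = np.sort(np.random.default_rng(0).uniform(0, 324, 8))
    np.testing.assert_allclose(deviations_ms(truth, truth), np.zeros(7))


def test_one_source_sample_is_four_ms_at_250hz():
    truth = np.arange(10.0, 18.0)
    pred = truth.copy()
    pred[0] += 324 / 300            # one source sample in resampled units
    d = deviations_ms(pred, truth, L_net=324, fs=250.0)
    assert d[0] == pytest.approx(4.0)


def test_resampled_deviation_back_mapping_hand_arithmetic():
    truth = np.arange(100.0, 108.0)
    pred = truth.copy()
    pred[6] += 13                   # +13 resampled samples at T peak
    d = deviations_ms(pred, truth, L_net=324, fs=250.0)
    assert d[5] == pytest.approx(13 * (300 / 324) * 4)
    without_map = deviations_ms(pred, truth, back_map=False)
    assert without_map[5] == pytest.approx(13 * 4)


def test_deviations_antisymmetry():
    rng = np.random.default_rng(1)
    truth = np.sort(rng.uniform(0, 324, (5, 8)), axis=1)
    pred = truth + rng.normal(0, 2, truth.shape)
    np.testing.assert_allclose(deviations_ms(pred, truth),
                               -deviations_ms(truth, pred))


def test_mae_of_means_reference_rows():
    # self-supervised per-point means
    assert mae_of_means([-0.24, -0.48, -0.28, -3.72, -4.12, -0.68, 1.34]) \
        == 1.55
    # two missing entries are averaged over the available five
    assert mae_of_means([16, 5, -10, np.nan, np.nan, -3, -16]) == 10.0
    assert mae_of_means([0, 0, 0]) == 0.0
    with pytest.raises(ValueError):
        mae_of_means([np.nan, np.nan])


def test_report_aggregates_and_mae():
    dev = np.array([[1.0, -2.0, 3.0, 0.0, 1.0, -1.0, 2.0],
                    [3.0, -4.0, 1.0, 2.0, -1.0, 1.0, 0.0]])
    rep = DeviationReport(dev)
    np.testing.assert_allclose(rep.mean, dev.mean(axis=0))
    np.testing.assert_allclose(rep.sd, dev.std(axis=0, ddof=1))
    np.testing.assert_allclose(rep.abs_mean, np.abs(dev).mean(axis=0))
    assert rep.mae_of_mean_deviation == mae_of_means(dev.mean(axis=0))
    assert list(rep.to_frame()["point"]) == list(REPORTED_POINTS)


def test_lead_selection_prefers_smaller_mean_abs_deviation():
    better = DeviationReport(np.full((4, 7), 2.0), lead="i")
    worse = DeviationReport(np.full((4, 7), 3.0), lead="ii")
    assert select_lead(better, worse) is better
    assert select_lead(worse, better) is better
    # deterministic tie-break to lead 1
    tie = DeviationReport(np.full((4, 7), 2.0), lead="ii")
    assert select_lead(better, tie) is better
    assert select_lead(better, None) is better


def test_lead_selection_per_record_enumeration():
    rng = np.random.default_rng(2)
    for _ in range(3):
        d1 = rng.normal(0, 1, (6, 7))
        d2 = rng.normal(0, 1, (6, 7))
        r1, r2 = DeviationReport(d1, "a"), DeviationReport(d2, "b")
        expect = r1 if np.abs(d1).mean() <= np.abs(d2).mean() else r2
        assert select_lead(r1, r2) is expect


def test_bland_altman_five_point_hand_fixture():
    truth = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
    pred = np.array([12.0, 19.0, 33.0, 38.0, 52.0])
    ba = bland_altman(pred, truth)
    diffs = pred - truth            # [2, -1, 3, -2, 2]
    m, s = diffs.mean(), diffs.std(ddof=1)
    assert ba.mean_diff == pytest.approx(m)
    assert ba.loa_lower == pytest.approx(m - 1.96 * s)
    assert ba.loa_upper == pytest.approx(m + 1.96 * s)
    assert ba.loa_lower <= ba.loa_upper
    np.testing.assert_allclose(ba.means, (pred + truth) / 2)


def test_bland_altman_offset_and_identity():
    truth = np.arange(5.0)
    ba = bland_altman(truth + 3.0, truth)
    assert ba.mean_diff == pytest.approx(3.0)
    assert ba.loa_width == pytest.approx(0.0)
    ba0 = bland_altman(truth, truth)
    assert ba0.mean_diff == 0.0 and ba0.loa_width == 0.0
    with pytest.raises(ValueError):
        bland_altman(np.array([1.0]), np.array([1.0]))


def test_loa_covers_about_95_percent_of_gaussian_differences():
    rng = np.random.default_rng(3)
    truth = rng.uniform(0, 300, 5000)
    pred = truth + rng.normal(0, 5, 5000)
    ba = bland_altman(pred, truth)
    inside = np.mean((ba.diffs >= ba.loa_lower) & (ba.diffs <= ba.loa_upper))
    assert inside >= 0.93


def test_regression_fit_closed_form():
    truth = np.array([1.0, 2.0, 3.0, 4.0])
    pred = np.array([1.1, 1.9, 3.2, 3.9])
    fit = regression_fit(pred, truth)
    # normal equations by hand
    xm, ym = truth.mean(), pred.mean()
    slope = np.sum((truth - xm) * (pred - ym)) / np.sum((truth - xm) ** 2)
    assert fit.slope == pytest.approx(slope)
    assert fit.intercept == pytest.approx(ym - slope * xm)

    ident = regression_fit(truth, truth)
    assert ident.slope == pytest.approx(1.0)
    assert ident.intercept == pytest.approx(0.0, abs=1e-12)
    assert ident.identity_distance == pytest.approx(0.0, abs=1e-12)
    assert regression_fit(2 * truth, truth).slope == pytest.approx(2.0)
    with pytest.raises(ValueError):
        regression_fit(truth, np.full(4, 2.0))
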