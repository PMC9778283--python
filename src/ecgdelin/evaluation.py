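"""Delineation error statistics and agreement analysis.

Signed deviations between predicted and reference fiducial positions are
measured in resampled-window samples, mapped back to source samples
(factor ``window_len / L_net``) and converted to milliseconds
(``1000 / fs``); at 250 Hz one source sample is exactly 4 ms. The R peak
is the windowing anchor and is excluded from reporting, leaving seven
points. Aggregates follow the m +/- sd convention; the scalar comparison
statistic is the mean of the absolute per-point mean deviations
("MAE of mean deviation"). Agreement uses Bland-Altman 95% limits
(mean difference +/- 1.96 sd) and least-squares regression of predicted
on annotated positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import L_NET, POINT_NAMES, WINDOW_LEN

#: the seven reported points (R peak excluded)
REPORTED_POINTS = tuple(p for i, p in enumerate(POINT_NAMES) if i != 4)
R_PEAK_INDEX = 4


def deviations_ms(pred, truth, L_net=L_NET, fs=250.0, window_len=WINDOW_LEN,
                  back_map=True):
    """Per-point signed deviations in ms, R peak dropped.

    ``pred`` and ``truth`` are (8,) or (n, 8) positions in resampled
    coordinates. With ``back_map`` (default) deviations are converted to
    source samples via ``window_len / L_net`` before the ms conversion,
    making 1 source sample exactly ``1000 / fs`` ms.
    """
    was_1d = np.ndim(pred) == 1
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape or pred.shape[1] != 8:
        raise ValueError("pred and truth must both be (n, 8)")
    d = pred - truth
    if back_map:
        d = d * (window_len / L_net)
    d = d * (1000.0 / fs)
    d = np.delete(d, R_PEAK_INDEX, axis=1)
    return d[0] if was_1d else d


def mae_of_means(per_point_means, decimals=2):
    """Mean absolute value of the per-point mean deviations.

    Missing entries (NaN) are skipped — methods that do not report every
    point are averaged over the points they do report. Rounded to the
    reporting precision (2 decimals, half away from zero).
    """
    vals = np.asarray(per_point_means, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("mae_of_means needs at least one available entry")
    mae = float(np.mean(np.abs(vals)))
    scale = 10.0 ** decimals
    return float(np.floor(mae * scale + 0.5) / scale)


@dataclass
class DeviationReport:
    """Per-point signed deviations (ms) with m +/- sd aggregates."""

    deviations: np.ndarray        # (n_beats, 7)
    lead: str = ""

    def __post_init__(self):
        self.deviations = np.atleast_2d(
            np.asarray(self.deviations, dtype=float))
        if self.deviations.shape[1] != len(REPORTED_POINTS):
            raise ValueError(
                f"expected {len(REPORTED_POINTS)} points per beat")

    @property
    def mean(self):
        return self.deviations.mean(axis=0)

    @property
    def sd(self):
        return self.deviations.std(axis=0, ddof=1) \
            if len(self.deviations) > 1 else np.zeros(len(REPORTED_POINTS))

    @property
    def abs_mean(self):
        return np.abs(self.deviations).mean(axis=0)

    @property
    def abs_sd(self):
        a = np.abs(self.deviations)
        return a.std(axis=0, ddof=1) if len(a) > 1 \
            else np.zeros(len(REPORTED_POINTS))

    @property
    def overall_abs_mean(self) -> float:
        return float(np.abs(self.deviations).mean())

    @property
    def mae_of_mean_deviation(self) -> float:
        return mae_of_means(self.mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"point": REPORTED_POINTS,
             "mean_ms": np.round(self.mean, 2),
             "sd_ms": np.round(self.sd, 2),
             "abs_mean_ms": np.round(self.abs_mean, 2),
             "abs_sd_ms": np.round(self.abs_sd, 2)})

    @classmethod
    def from_positions(cls, pred, truth, L_net=L_NET, fs=250.0,
                       back_map=True, lead=""):
        return cls(deviations_ms(np.atleast_2d(pred), np.atleast_2d(truth),
                                 L_net=L_net, fs=fs, back_map=back_map),
                   lead=lead)


def select_lead(report_lead1: DeviationReport,
                report_lead2: DeviationReport | None) -> DeviationReport:
    """Per-recording lead selection: the lead with the smaller overall
    mean absolute deviation wins; ties go to lead 1."""
    if report_lead2 is None:
        return report_lead1
    return report_lead2 if (report_lead2.overall_abs_mean
                            < report_lead1.overall_abs_mean) \
        else report_lead1


@dataclass
class BlandAltman:
    """Mean difference and 95% limits of agreement."""

    mean_diff: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray             # (pred + truth) / 2, for plotting
    diffs: np.ndarray             # pred - truth

    @property
    def loa_width(self) -> float:
        return self.loa_upper - self.loa_lower


def bland_altman(pred, truth) -> BlandAltman:
    """Bland-Altman agreement: differences, their mean, and the limits
    mean +/- 1.96 * sd (sample sd, ddof=1)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    diffs = pred - truth
    m = float(diffs.mean())
    s = float(diffs.std(ddof=1))
    return BlandAltman(m, m - 1.96 * s, m + 1.96 * s,
                       (pred + truth) / 2.0, diffs)


@dataclass
class RegressionFit:
    slope: float
    intercept: float

    @property
    def identity_distance(self) -> float:
        """|slope - 1| + |intercept|: closeness of the trend line to y=x."""
        return abs(self.slope - 1.0) + abs(self.intercept)

    def line(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def regression_fit(pred, truth) -> RegressionFit:
    """Least-squares line of predicted on annotated positions."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size != truth.size or pred.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    if np.var(truth) == 0:
        raise ValueError("annotated positions have zero variance")
    slope, intercept = np.polyfit(truth, pred, 1)
    return RegressionFit(float(slope), float(intercept))


# ---------------------------------------------------------------------------
# Plots (matplotlib)
# ---------------------------------------------------------------------------

def plot_bland_altman(ba: BlandAltman, ax=None, title=""):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.means, ba.diffs, s=8, alpha=0.6)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_lower, "--"),
                     (ba.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of predicted and annotated position")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    return ax


def plot_regression(pred, truth, ax=None, title=""):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    fit = regression_fit(pred, truth)
    ax.scatter(truth, pred, s=8, alpha=0.6)
    grid = np.linspace(np.min(truth), np.max(truth), 2)
    ax.plot(grid, fit.line(grid), color="C1",
            label=f"fit: y={fit.slope:.2f}x+{fit.intercept:.2f}")
    ax.plot(grid, grid, color="gray", linestyle="--", label="y=x")
    ax.set_xlabel("annotated position")
    ax.set_ylabel("predicted position")
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
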