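"""Synthetic ECG beats with analytically known fiducial points.

Each wave (P, Q, R, S, T) is a Gaussian bump a*exp(-(t-mu)^2 / (2 b^2)).
Peak truths sit at the Gaussian centres of P, R and T; onset/offset
truths sit at centre -/+ 3 sigma of the outermost P/QRS/T Gaussians
(beyond 3 sigma a Gaussian carries <0.3% of its peak amplitude, so the
definition is deterministic and morphology-independent). Everything
downstream — denoising, segmentation, training, evaluation — can
therefore be tested against ground truth known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import FiducialLabels, POINT_NAMES, round_half_away

WAVE_ORDER = "PQRST"


@dataclass(frozen=True)
class WaveSpec:
    """One Gaussian wave: amplitude (mV), centre and width (seconds)."""

    label: str
    amplitude: float
    center: float
    width: float

    def __post_init__(self):
        if self.label not in WAVE_ORDER:
            raise ValueError(f"wave label must be one of {WAVE_ORDER!r}")
        if self.width <= 0:
            raise ValueError("wave width must be positive")


@dataclass
class SyntheticBeat:
    samples: np.ndarray
    fs: float
    truth: FiducialLabels
    seed: int


def default_waves() -> list[WaveSpec]:
    """A normal-morphology beat on a 1.2 s window with the R peak at
    0.4 s (100 samples at 250 Hz), matching the downstream window."""
    return [
        WaveSpec("P", 0.15, 0.20, 0.020),
        WaveSpec("Q", -0.10, 0.37, 0.008),
        WaveSpec("R", 1.00, 0.40, 0.012),
        WaveSpec("S", -0.15, 0.43, 0.009),
        WaveSpec("T", 0.30, 0.75, 0.050),
    ]


def _check_waves(waves):
    order = {w.label: w for w in waves}
    if len(order) != len(waves):
        raise ValueError("duplicate wave labels")
    centers = [w.center for w in sorted(waves,
                                        key=lambda w: WAVE_ORDER.index(w.label))]
    if np.any(np.diff(centers) <= 0):
        raise ValueError("wave centres must increase in P<Q<R<S<T order")
    return order


def _truth_positions(order: dict, fs: float, length: int) -> np.ndarray:
    """Truth in samples: peaks at centres, onsets/offsets at -/+3 sigma."""
    def at(sec):
        return float(np.clip(round_half_away(sec * fs), 0, length - 1))

    pos = np.full(8, np.nan)
    if "P" in order:
        p = order["P"]
        pos[0] = at(p.center - 3 * p.width)
        pos[1] = at(p.center)
        pos[2] = at(p.center + 3 * p.width)
    qrs = [order[k] for k in "QRS" if k in order]
    if qrs:
        first, last = qrs[0], qrs[-1]
        pos[3] = at(first.center - 3 * first.width)
        pos[5] = at(last.center + 3 * last.width)
        if "R" in order:
            pos[4] = at(order["R"].center)
    if "T" in order:
        t = order["T"]
        pos[6] = at(t.center)
        pos[7] = at(t.center + 3 * t.width)
    return pos


def generate_beat(waves=None, fs=250.0, length=300, noise_sd=0.0,
                  seed=0) -> SyntheticBeat:
    """Generate one beat as a sum of Gaussian waves plus white noise.

    Deterministic given ``seed``. Raises ``ValueError`` when the wave
    layout would invert the fiducial ordering (e.g. overlapping 3-sigma
    supports of P and QRS).
    """
    if waves is None:
        waves = default_waves()
    if length < 2 or fs <= 0:
        raise ValueError("need length >= 2 and fs > 0")
    order = _check_waves(waves)
    t = np.arange(length) / fs
    samples = np.zeros(length)
    for w in waves:
        samples += w.amplitude * np.exp(-((t - w.center) ** 2) /
                                        (2 * w.width ** 2))
    if noise_sd > 0:
        samples = samples + np.random.default_rng(seed).normal(
            0.0, noise_sd, length)
    truth = FiducialLabels(_truth_positions(order, fs, length))
    return SyntheticBeat(samples, fs, truth, seed)


def beat_span_seconds(waves) -> float:
    """Extent of the beat template from t=0 to the last 3-sigma edge."""
    return max(w.center + 3 * w.width for w in waves)


def generate_record(n_beats, rr_mean, rr_sd, waves=None, fs=250.0, seed=0,
                    noise_sd=0.0, baseline_amp=0.0, baseline_freq=0.25,
                    beat_len=300):
    """A beat train with jittered RR intervals and optional baseline wander.

    Returns ``(signal, truths)`` where ``truths`` is one
    :class:`FiducialLabels` per beat, already shifted to record
    coordinates. ``rr_mean`` must exceed the beat template span.
    """
    if n_beats < 1:
        raise ValueError("need at least one beat")
    if waves is None:
        waves = default_waves()
    span = beat_span_seconds(waves)
    if rr_mean <= span:
        raise ValueError(
            f"rr_mean ({rr_mean} s) must exceed the beat span ({span:.3f} s)")
    rng = np.random.default_rng(seed)
    rr = np.maximum(rng.normal(rr_mean, rr_sd, n_beats - 1), span) \
        if n_beats > 1 else np.empty(0)
    offsets = np.concatenate([[0], np.cumsum(round_half_away(rr * fs))]
                             ).astype(int)
    length = offsets[-1] + beat_len
    signal = np.zeros(length)
    t = np.arange(length) / fs
    truths = []
    base = generate_beat(waves, fs=fs, length=beat_len, noise_sd=0.0)
    for off in offsets:
        signal[off: off + beat_len] += base.samples
        truths.append(base.truth.shifted(off))
    if baseline_amp > 0:
        if not 0 < baseline_freq < 0.5:
            raise ValueError("baseline wander frequency must be in (0, 0.5) Hz")
        signal += baseline_amp * np.sin(2 * np.pi * baseline_freq * t)
    if noise_sd > 0:
        signal += rng.normal(0.0, noise_sd, length)
    return signal, truths


def generate_population(n_beats, fs=250.0, length=300, noise_sd=0.02,
                        amp_jitter=0.15, time_jitter=0.012, width_jitter=0.10,
                        seed=0) -> list[SyntheticBeat]:
    """Independent beats with beat-to-beat morphological variability.

    Amplitudes, wave centres (except the R anchor) and widths are
    jittered around the default template so the landmark-regression task
    is non-trivial; the R peak stays at 0.4 s, the windowing anchor.
    """
    rng = np.random.default_rng(seed)
    beats = []
    while len(beats) < n_beats:
        waves = []
        for w in default_waves():
            amp = w.amplitude * (1 + rng.uniform(-amp_jitter, amp_jitter))
            center = w.center if w.label == "R" else \
                w.center + rng.normal(0.0, time_jitter)
            width = w.width * (1 + rng.uniform(-width_jitter, width_jitter))
            waves.append(WaveSpec(w.label, amp, center, width))
        seed_i = int(rng.integers(0, 2 ** 31 - 1))
        try:
            beats.append(generate_beat(waves, fs=fs, length=length,
                                       noise_sd=noise_sd, seed=seed_i))
        except ValueError:
            continue  # jitter occasionally inverts the ordering; redraw
    return beats


def truth_table(truths) -> pd.DataFrame:
    """Plain CSV-ready truth table: beat_index plus the 8 positions."""
    rows = [t.positions if isinstance(t, FiducialLabels) else t.truth.positions
            for t in truths]
    df = pd.DataFrame(rows, columns=list(POINT_NAMES))
    df.insert(0, "beat_index", np.arange(len(rows)))
    return df


def write_record(directory, name, signal, fs, truths, lead_names=("MLII",)):
    """Write a WFDB-compatible record, wave annotations mirroring the
    QT-database symbol scheme, and a CSV truth table."""
    from . import data_io

    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.shape[0] > signal.shape[1]:
        signal = signal.T
    data_io.write_wfdb_record(directory, name, signal.T, fs,
                              lead_names=list(lead_names))
    positions, symbols = [], []
    marks = ["(", "p", ")", "(", "N", ")", "t", ")"]
    for tr in truths:
        pos = tr.positions if isinstance(tr, FiducialLabels) else tr
        for p, s in zip(pos, marks):
            if np.isfinite(p):
                positions.append(int(p))
                symbols.append(s)
    data_io.write_wfdb_annotations(directory, name, positions, symbols)
    truth_table(truths).to_csv(f"{directory}/{name}_truth.csv", index=False)
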