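"""Beat preprocessing: wavelet denoising, R-peak-centred windowing,
resampling to the network input length, and fiducial label mapping.

The downstream window spans 100 samples before the annotated R peak and
200 after (1.2 s at 250 Hz); windows are then resampled to ``L_NET``
samples. Fiducial positions ride along through the same affine map and
are rounded half-away-from-zero, identically at train and eval time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

#: canonical order of the eight fiducial points
POINT_NAMES = ("P-on", "P-peak", "P-off", "QRS-on", "R-peak", "QRS-off",
               "T-peak", "T-off")

#: network input length (the halving chain 324 -> 162 -> 81 is exact)
L_NET = 324
#: pretext beats keep the raw cut length
PRETEXT_LEN = 300
#: window extent around the R peak, in source samples at 250 Hz
PRE_SAMPLES, POST_SAMPLES = 100, 200
WINDOW_LEN = PRE_SAMPLES + POST_SAMPLES


class BeatRejected(Exception):
    """A beat window that cannot be used (out of range, degenerate, ...)."""


def round_half_away(x):
    """Round to nearest integer, halves away from zero."""
    x = np.asarray(x, dtype=float)
    return np.where(np.isnan(x), np.nan,
                    np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class FiducialLabels:
    """Eight ordered landmark positions in sample coordinates.

    Order: P-on, P-peak, P-off, QRS-on, R-peak, QRS-off, T-peak, T-off.
    Entries may be NaN for points a source does not annotate; the finite
    entries must be strictly increasing.
    """

    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float).reshape(8)
        finite = pos[np.isfinite(pos)]
        if finite.size and np.any(np.diff(finite) <= 0):
            raise ValueError(
                f"fiducial positions must be strictly increasing, got {pos}")
        self.positions = pos

    def shifted(self, offset: float) -> "FiducialLabels":
        return FiducialLabels(self.positions + offset)

    def as_dict(self) -> dict:
        return dict(zip(POINT_NAMES, self.positions))


@dataclass
class BeatSegment:
    """One fixed-length beat window with sampling metadata."""

    samples: np.ndarray
    source_fs: float = 250.0
    source_len: int = WINDOW_LEN
    lead: str = ""
    record_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("beat segment contains non-finite samples")


def dwt_denoise(signal, fs=250.0, wavelet="db6", level=8,
                drop_approximation=True, drop_details=2):
    """Wavelet-denoise an ECG strip.

    The signal is decomposed with the db6 mother wavelet to ``level``
    scales (capped at the maximum usable level for the signal length);
    the deepest approximation band (baseline wander) and the
    ``drop_details`` finest detail bands (high-frequency noise) are
    zeroed before reconstruction. Output length equals input length.
    """
    signal = np.asarray(signal, dtype=float)
    w = pywt.Wavelet(wavelet)
    if signal.size < w.dec_len:
        raise ValueError(
            f"signal of {signal.size} samples is shorter than the {wavelet} "
            f"filter support ({w.dec_len})")
    level = min(level, pywt.dwt_max_level(signal.size, w))
    if level < 1:
        raise ValueError("signal too short for one decomposition level")
    coeffs = pywt.wavedec(signal, w, level=level)
    if drop_approximation:
        coeffs[0] = np.zeros_like(coeffs[0])
    for i in range(1, min(drop_details, level) + 1):
        coeffs[-i] = np.zeros_like(coeffs[-i])
    return pywt.waverec(coeffs, w)[: signal.size]


def segment_beat(signal, r_peak, pre=PRE_SAMPLES, post=POST_SAMPLES):
    """Cut the window ``[r_peak - pre, r_peak + post)`` around an R peak.

    Raises :class:`BeatRejected` when the window does not fit.
    """
    signal = np.asarray(signal, dtype=float)
    r_peak = int(r_peak)
    if r_peak - pre < 0 or r_peak + post > signal.size:
        raise BeatRejected(
            f"window [{r_peak - pre}, {r_peak + post}) outside record of "
            f"length {signal.size}")
    return signal[r_peak - pre: r_peak + post]


def resample_beat(window, target_len, source_fs=250.0, lead="",
                  record_id="") -> BeatSegment:
    """Linearly resample a raw window to ``target_len`` samples.

    Endpoints are preserved exactly by the linear interpolation grid.
    """
    window = np.asarray(window, dtype=float)
    if target_len < 2:
        raise ValueError("target_len must be at least 2")
    if window.size < 2:
        raise ValueError("window must have at least 2 samples")
    grid = np.linspace(0.0, window.size - 1, target_len)
    samples = np.interp(grid, np.arange(window.size), window)
    return BeatSegment(samples, source_fs=source_fs, source_len=window.size,
                       lead=lead, record_id=record_id)


def map_labels(positions_original, r_peak, target_len,
               pre=PRE_SAMPLES, window_len=WINDOW_LEN) -> FiducialLabels:
    """Map fiducial positions from record coordinates into the resampled
    window: ``pos' = round((pos - (r_peak - pre)) * target_len / window_len)``.

    Beats with any point outside the window, or whose mapped points
    collide after rounding, are rejected.
    """
    pos = np.asarray(positions_original, dtype=float).reshape(8)
    start = int(r_peak) - pre
    rel = pos - start
    finite = np.isfinite(rel)
    if np.any((rel[finite] < 0) | (rel[finite] >= window_len)):
        raise BeatRejected("fiducial point outside the beat window")
    mapped = round_half_away(rel * (target_len / window_len))
    try:
        return FiducialLabels(mapped)
    except ValueError as exc:
        raise BeatRejected(str(exc)) from exc


def normalize_beat(segment):
    """Zero-mean, unit-variance scaling of one beat (affine invariant)."""
    arr = segment.samples if isinstance(segment, BeatSegment) else \
        np.asarray(segment, dtype=float)
    sd = arr.std()
    if sd == 0:
        raise BeatRejected("zero-variance beat window")
    out = (arr - arr.mean()) / sd
    if isinstance(segment, BeatSegment):
        return BeatSegment(out, segment.source_fs, segment.source_len,
                           segment.lead, segment.record_id)
    return out


def prepare_downstream(signal, r_peaks, labels_list, fs=250.0, target_len=L_NET,
                       denoise=True, normalize=False, lead="", record_id=""):
    """Full downstream path: denoise, window, resample, map labels.

    Returns ``(X, Y, kept)`` where ``X`` is (n, target_len), ``Y`` is
    (n, 8) mapped fiducials and ``kept`` the surviving beat indices;
    rejected beats (window off the record edge, labels out of window,
    degenerate amplitude) are skipped, not fatal.

    Per-beat amplitude normalization is available but off by default:
    the pretext stage must see raw amplitudes (otherwise the scaling
    transformation is unlearnable), and a backbone transferred from it
    expects the same input distribution downstream.
    """
    signal = np.asarray(signal, dtype=float)
    if denoise:
        signal = dwt_denoise(signal, fs)
    X, Y, kept = [], [], []
    for i, (r, lab) in enumerate(zip(r_peaks, labels_list)):
        pos = lab.positions if isinstance(lab, FiducialLabels) else lab
        try:
            window = segment_beat(signal, r)
            seg = resample_beat(window, target_len, source_fs=fs, lead=lead,
                                record_id=record_id)
            mapped = map_labels(pos, r, target_len)
            if normalize:
                seg = normalize_beat(seg)
        except BeatRejected:
            continue
        X.append(seg.samples)
        Y.append(mapped.positions)
        kept.append(i)
    if not X:
        return (np.empty((0, target_len)), np.empty((0, 8)), [])
    return np.stack(X), np.stack(Y), kept


def prepare_pretext_beats(signal, r_peaks, fs=250.0, target_len=PRETEXT_LEN,
                          denoise=False):
    """Cut beats for the pretext task: a 1.2 s window (0.4 s before the R
    peak, 0.8 s after, converted to the source sampling rate) resampled
    to ``target_len``. No amplitude normalization — the scaling
    transformation must stay recognizable."""
    signal = np.asarray(signal, dtype=float)
    if denoise:
        signal = dwt_denoise(signal, fs)
    pre = int(round(0.4 * fs))
    post = int(round(0.8 * fs))
    beats = []
    for r in r_peaks:
        try:
            window = segment_beat(signal, r, pre=pre, post=post)
        except BeatRejected:
            continue
        beats.append(resample_beat(window, target_len, source_fs=fs).samples)
    return np.stack(beats) if beats else np.empty((0, target_len))
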