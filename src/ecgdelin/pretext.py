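"""Transformation-recognition pretext dataset.

Every beat yields four samples: the untransformed signal (pseudo-label 0)
and its noise-added (1), amplitude-scaled (2) and time-inverted (3)
versions, in that fixed order. The pseudo-labels are generated purely by
the transformation applied — no human annotation enters the pretext
stage. Beats on this path are deliberately NOT amplitude-normalized,
otherwise the scaling class would be unlearnable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: pseudo-label -> transformation name, in the fixed application order
LABEL_NAMES = {0: "original", 1: "noise", 2: "scaling", 3: "inversion"}

#: default noise level: visible but morphology-preserving
DEFAULT_SNR_DB = 15.0
#: default scaling factors, drawn away from 1 so class 2 is separable
DEFAULT_FACTOR_RANGES = ((0.5, 0.8), (1.25, 2.0))


@dataclass
class PretextSample:
    signal: np.ndarray
    label: int

    def __post_init__(self):
        if self.label not in LABEL_NAMES:
            raise ValueError("pretext label must be in {0, 1, 2, 3}")
        self.signal = np.asarray(self.signal, dtype=float)


def add_noise(signal, snr_db, seed=0):
    """Add white Gaussian noise at an exact output signal-to-noise ratio.

    The drawn noise vector is rescaled so the empirical SNR equals
    ``snr_db``; ``snr_db=inf`` is the identity.
    """
    signal = np.asarray(signal, dtype=float)
    power = float(np.mean(signal ** 2))
    if power == 0:
        raise ValueError("cannot define an SNR for a zero-power signal")
    if np.isinf(snr_db):
        return signal.copy()
    noise = np.random.default_rng(seed).normal(0.0, 1.0, signal.shape)
    target_power = power / (10.0 ** (snr_db / 10.0))
    noise *= np.sqrt(target_power / np.mean(noise ** 2))
    return signal + noise


def scale(signal, factor):
    """Pointwise amplitude scaling by a positive factor."""
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    return np.asarray(signal, dtype=float) * factor


def invert_time(signal):
    """Reverse the sample order (an involution)."""
    return np.asarray(signal, dtype=float)[::-1].copy()


def draw_scale_factor(rng, ranges=DEFAULT_FACTOR_RANGES) -> float:
    """Uniform draw from a union of intervals, weighted by their lengths."""
    widths = np.array([hi - lo for lo, hi in ranges], dtype=float)
    if widths.sum() > 0:
        lo, hi = ranges[rng.choice(len(ranges), p=widths / widths.sum())]
    else:                       # degenerate point intervals: uniform choice
        lo, hi = ranges[rng.choice(len(ranges))]
    return float(rng.uniform(lo, hi))


def build_pretext_dataset(beats, snr_db=DEFAULT_SNR_DB,
                          factor_ranges=DEFAULT_FACTOR_RANGES, seed=0):
    """Build the 4-class dataset: 4 samples per beat, labels 0-3.

    Scaling factors are drawn per beat; noise seeds derive from ``seed``.
    Identical transformed signals (e.g. factor 1, infinite SNR) are kept,
    never deduplicated — class separability comes from the parameters.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for beat in beats:
        beat = np.asarray(beat, dtype=float)
        noise_seed = int(rng.integers(0, 2 ** 31 - 1))
        factor = draw_scale_factor(rng, factor_ranges)
        samples.append(PretextSample(beat.copy(), 0))
        samples.append(PretextSample(add_noise(beat, snr_db, noise_seed), 1))
        samples.append(PretextSample(scale(beat, factor), 2))
        samples.append(PretextSample(invert_time(beat), 3))
    return samples


def dataset_arrays(samples):
    """Stack a pretext dataset into (X, y) arrays."""
    if not samples:
        return np.empty((0, 0)), np.empty(0, dtype=int)
    X = np.stack([s.signal for s in samples])
    y = np.asarray([s.label for s in samples], dtype=int)
    return X, y
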