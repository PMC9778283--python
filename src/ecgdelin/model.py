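"""Model/results objects: the public fitting surface.

:class:`PretextClassifier` wraps the transformation-recognition stage;
its :meth:`~PretextClassifier.fit` returns :class:`PretextResults`
carrying the cross-validated accuracies and the transferable backbone.
:class:`FiducialRegressor` wraps downstream fine-tuning (optionally from
a pretrained backbone, with the convolutional layers frozen); its
results object carries held-out predictions, the per-point deviation
report, Bland-Altman agreement and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluation
from .evaluation import (BlandAltman, DeviationReport, bland_altman,
                         regression_fit)
from .nn import DelineationNet, NetConfig
from .preprocess import L_NET, POINT_NAMES
from .pretext import build_pretext_dataset, dataset_arrays
from .training import (DownstreamResult, PretextCheckpoint, TrainConfig,
                       train_downstream, train_pretext, transfer_and_freeze)


class PretextClassifier:
    """Transformation-recognition model over unlabeled beats.

    Parameters
    ----------
    signals, labels:
        Pre-built 4-class dataset ((n, length) array, integer labels), or
        use :meth:`from_beats` to generate the transformed dataset from
        raw beats.
    net_config:
        Architecture; defaults to the reduced CPU-scale configuration at
        the beat length.
    """

    def __init__(self, signals, labels, net_config: NetConfig | None = None):
        self.signals = np.asarray(signals, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        if len(self.signals) != len(self.labels):
            raise ValueError("signals and labels must align")
        self.net_config = (net_config or
                           NetConfig.reduced(input_len=self.signals.shape[1])
                           ).with_head("pretext")

    @classmethod
    def from_beats(cls, beats, snr_db=15.0, seed=0,
                   net_config: NetConfig | None = None):
        X, y = dataset_arrays(build_pretext_dataset(beats, snr_db=snr_db,
                                                    seed=seed))
        return cls(X, y, net_config=net_config)

    def fit(self, train_config: TrainConfig | None = None) -> "PretextResults":
        cfg = train_config or TrainConfig()
        checkpoint = train_pretext(self.signals, self.labels,
                                   self.net_config, cfg)
        return PretextResults(self, checkpoint, cfg)


@dataclass
class PretextResults:
    model: PretextClassifier
    checkpoint: PretextCheckpoint
    train_config: TrainConfig

    @property
    def fold_accuracies(self):
        return self.checkpoint.fold_accuracies

    @property
    def mean_accuracy(self) -> float:
        return self.checkpoint.mean_accuracy

    def summary(self) -> str:
        lines = ["Pretext transformation-recognition results",
                 "=" * 44,
                 f"samples: {len(self.model.signals)}   "
                 f"folds: {self.train_config.folds}"]
        for i, acc in enumerate(self.fold_accuracies):
            lines.append(f"fold {i}: validation accuracy {acc:.3f}")
        lines.append(f"mean validation accuracy: {self.mean_accuracy:.3f}")
        return "\n".join(lines)


class FiducialRegressor:
    """Eight-point landmark regression on fixed-length beat windows.

    Parameters
    ----------
    beats : (n, L) array
        Preprocessed beat windows (denoised, resampled, normalized).
    labels : (n, 8) array
        Fiducial positions in resampled coordinates.
    pretrained : PretextResults, PretextCheckpoint, or backbone state dict
        Convolutional backbone to transfer; ``None`` trains from scratch.
    freeze_backbone : bool
        With a pretrained backbone, freeze it and fine-tune only the
        fully connected head (the default transfer protocol).
    """

    def __init__(self, beats, labels, net_config: NetConfig | None = None,
                 pretrained=None, freeze_backbone=True):
        self.beats = np.asarray(beats, dtype=float)
        self.labels = np.asarray(labels, dtype=float)
        if len(self.beats) != len(self.labels) or self.labels.shape[1] != 8:
            raise ValueError("need aligned beats and (n, 8) labels")
        self.net_config = (net_config or
                           NetConfig.reduced(input_len=self.beats.shape[1])
                           ).with_head("regression")
        if isinstance(pretrained, PretextResults):
            pretrained = pretrained.checkpoint
        self.pretrained = pretrained
        self.freeze_backbone = freeze_backbone

    def _build_net(self, seed) -> DelineationNet:
        if self.pretrained is not None:
            return transfer_and_freeze(self.pretrained, self.net_config,
                                       seed=seed, freeze=self.freeze_backbone)
        return DelineationNet(self.net_config,
                              rng=np.random.default_rng(seed))

    def fit(self, train_config: TrainConfig | None = None
            ) -> "DelineationResults":
        cfg = train_config or TrainConfig(lr=0.001)
        net = self._build_net(cfg.seed)
        result = train_downstream(net, self.beats, self.labels, cfg)
        return DelineationResults(self, result, cfg)


class DelineationResults:
    """Fitted delineator: held-out predictions and error statistics."""

    def __init__(self, model: FiducialRegressor, result: DownstreamResult,
                 train_config: TrainConfig):
        self.model = model
        self._result = result
        self.train_config = train_config
        self.net = result.net

    # -- basic quantities ------------------------------------------------
    @property
    def best_val_l1(self) -> float:
        return self._result.best_val_l1

    @property
    def test_l1(self) -> float:
        return self._result.test_l1

    @property
    def test_idx(self):
        return self._result.test_idx

    @property
    def test_predictions(self):
        return self._result.test_predictions

    @property
    def test_truth(self):
        return self.model.labels[self.test_idx]

    def predict(self, beats) -> np.ndarray:
        """Predicted fiducial positions (resampled coordinates)."""
        self.net.eval()
        return self.net(np.asarray(beats, dtype=float)).data

    # -- statistics ------------------------------------------------------
    def deviation_report(self, fs=250.0, back_map=True) -> DeviationReport:
        L_net = self.model.net_config.input_len
        return DeviationReport.from_positions(
            self.test_predictions, self.test_truth, L_net=L_net, fs=fs,
            back_map=back_map)

    def bland_altman(self, point: str | int) -> BlandAltman:
        idx = POINT_NAMES.index(point) if isinstance(point, str) else point
        return bland_altman(self.test_predictions[:, idx],
                            self.test_truth[:, idx])

    def regression(self, point: str | int):
        idx = POINT_NAMES.index(point) if isinstance(point, str) else point
        return regression_fit(self.test_predictions[:, idx],
                              self.test_truth[:, idx])

    def summary(self, fs=250.0) -> str:
        rep = self.deviation_report(fs=fs)
        df = rep.to_frame()
        lines = ["Fiducial delineation results (held-out beats)",
                 "=" * 56,
                 f"beats: {len(self.model.beats)}   "
                 f"held out: {len(self.test_idx)}   "
                 f"pretrained backbone: "
                 f"{'yes' if self.model.pretrained is not None else 'no'}"
                 f"{' (frozen)' if self.model.pretrained is not None and self.model.freeze_backbone else ''}",
                 f"validation L1: {self.best_val_l1:.3f} samples   "
                 f"test L1: {self.test_l1:.3f} samples",
                 "",
                 df.to_string(index=False),
                 "",
                 f"MAE of mean deviation: "
                 f"{rep.mae_of_mean_deviation:.2f} ms"]
        return "\n".join(lines)

    # -- plots -----------------------------------------------------------
    def plot_bland_altman(self, point, ax=None):
        name = point if isinstance(point, str) else POINT_NAMES[point]
        return evaluation.plot_bland_altman(self.bland_altman(point), ax=ax,
                                            title=name)

    def plot_regression(self, point, ax=None):
        idx = POINT_NAMES.index(point) if isinstance(point, str) else point
        name = POINT_NAMES[idx]
        return evaluation.plot_regression(self.test_predictions[:, idx],
                                          self.test_truth[:, idx], ax=ax,
                                          title=name)
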