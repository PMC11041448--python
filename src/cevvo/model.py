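"""CEVVO classifier (model/results objects), training loop, loss and baselines.

The main entry point is :class:`CevvoClassifier`, built from preprocessed,
scaled samples; its :meth:`~CevvoClassifier.fit` returns a
:class:`CevvoResults` carrying the trained network, the training history and a
``summary()`` table, and scoring new samples through
:meth:`CevvoResults.predict`.  Four reference classifiers (logistic regression,
naive Bayes, a dense network and a decision tree) consume the flattened
concatenation of temporal and static features under the same train/test
protocol via :func:`fit_baseline`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .cohort import Sample
from .nn import Adam, CevvoNetwork

__all__ = [
    "ModelConfig", "Prediction", "CevvoClassifier", "CevvoResults",
    "build_model", "bce_loss", "train", "predict",
    "fit_baseline", "BaselineResults", "flatten_features", "BASELINE_KINDS",
]

BASELINE_KINDS = ("logistic_regression", "naive_bayes", "dense_network",
                  "decision_tree")
_SCORE_EPS = 1e-7


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    Defaults are the full-scale architecture: static dense widths (32, 33, 25),
    1024 convolution filters and LSTM units (fusion width 25 + 1024 = 1049).
    ``small()`` gives a desk-scale profile (width-32 temporal head) exercising
    identical code paths.
    """

    static_widths: tuple = (32, 33, 25)
    temporal_filters: int = 1024
    lstm_units: int = 1024
    recon_loss_weight: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.static_widths) < 1 or self.temporal_filters < 1 \
                or self.lstm_units < 1:
            raise ValueError("all widths must be >= 1")
        if self.recon_loss_weight < 0:
            raise ValueError("recon_loss_weight must be >= 0")

    @property
    def fusion_width(self) -> int:
        return self.static_widths[-1] + self.lstm_units

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Desk-scale profile: width-32 temporal head, shorter training."""
        base = dict(temporal_filters=32, lstm_units=32, max_epochs=40,
                    patience=8, batch_size=36)
        base.update(overrides)
        return cls(**base)


@dataclass
class Prediction:
    """A sigmoid score for one sample, with its identifying metadata."""

    patient_id: str
    truncation_fraction: float
    score: float
    label: int
    end_day: float = float("nan")

    def __post_init__(self):
        if not 0.0 < self.score < 1.0:
            raise ValueError("score must lie strictly inside (0, 1)")


def bce_loss(labels, scores) -> float:
    """Mean binary cross-entropy; scores clipped to [1e-7, 1 - 1e-7]."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(scores, dtype=float), _SCORE_EPS, 1.0 - _SCORE_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _pack(samples: Sequence[Sample]):
    S = np.stack([s.static_vec for s in samples])
    X = np.stack([s.series for s in samples])
    y = np.array([s.label for s in samples], dtype=float)
    return S, X, y


def build_model(config: ModelConfig, static_dim: int = 32, n_channels: int = 8,
                rng: np.random.Generator | None = None) -> CevvoNetwork:
    """Instantiate the two-headed network for the given configuration."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return CevvoNetwork(
        static_dim=static_dim, static_widths=config.static_widths,
        n_channels=n_channels, conv_filters=config.temporal_filters,
        lstm_units=config.lstm_units, recon_weight=config.recon_loss_weight,
        rng=rng)


def train(model: CevvoNetwork, train_samples: Sequence[Sample],
          val_samples: Sequence[Sample] | None, config: ModelConfig) -> dict:
    """Minibatch Adam training with early stopping on validation loss.

    Returns a history dict (per-epoch train/validation losses, epochs run, the
    best epoch).  The model is left at the best-validation-loss parameters (or
    the final parameters when no validation set is given).
    """
    if not train_samples:
        raise ValueError("empty training split")
    ids_train = {s.patient_id for s in train_samples}
    if val_samples and ids_train & {s.patient_id for s in val_samples}:
        raise ValueError("train and validation splits share patients")
    rng = np.random.default_rng(config.seed)
    S, X, y = _pack(train_samples)
    val = _pack(val_samples) if val_samples else None
    opt = Adam(model.params, lr=config.learning_rate)
    n = len(train_samples)
    history = {"train_loss": [], "val_loss": []}
    best_loss, best_params, best_epoch, since_best = np.inf, None, 0, 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = model.gradients(S[idx], X[idx], y[idx])
            opt.step(model.params, grads)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if val is not None:
            vloss = float(model.loss(*val))
            history["val_loss"].append(vloss)
            if vloss < best_loss - 1e-9:
                best_loss, best_params, best_epoch = vloss, model.copy_params(), epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if best_params is not None:
        model.set_params(best_params)
    history["epochs_run"] = len(history["train_loss"])
    history["best_epoch"] = best_epoch if val is not None else history["epochs_run"] - 1
    return history


def _batched_scores(model: CevvoNetwork, samples: Sequence[Sample],
                    batch_size: int = 256) -> np.ndarray:
    S, X, _ = _pack(samples)
    if np.abs(X).max(initial=0.0) > 50 or np.abs(S).max(initial=0.0) > 50:
        warnings.warn("inputs look unscaled (values far outside [0, 1]); "
                      "did you apply the training scaler?", stacklevel=2)
    scores = np.empty(len(samples))
    for start in range(0, len(samples), batch_size):
        sl = slice(start, start + batch_size)
        scores[sl] = model.forward(S[sl], X[sl])[0]
    return scores


def predict(model: CevvoNetwork, samples: Sequence[Sample]) -> list[Prediction]:
    """Score samples (order-preserving, batch-size invariant)."""
    scores = np.clip(_batched_scores(model, samples),
                     _SCORE_EPS, 1.0 - _SCORE_EPS)
    return [Prediction(patient_id=s.patient_id,
                       truncation_fraction=s.truncation_fraction,
                       score=float(p), label=s.label, end_day=s.end_day)
            for s, p in zip(samples, scores)]


class CevvoClassifier:
    """Decannulation-outcome classifier over preprocessed, scaled samples.

    Parameters
    ----------
    train_samples, val_samples
        Disjoint (at patient level) splits of scaled :class:`~cevvo.cohort.Sample`
        objects.  The validation split drives early stopping; it may be omitted.
    config
        :class:`ModelConfig`; defaults to the full-scale architecture.
    """

    def __init__(self, train_samples: Sequence[Sample],
                 val_samples: Sequence[Sample] | None = None,
                 config: ModelConfig | None = None):
        if not train_samples:
            raise ValueError("empty training split")
        self.train_samples = list(train_samples)
        self.val_samples = list(val_samples) if val_samples else None
        self.config = config or ModelConfig()
        self.static_dim = self.train_samples[0].static_vec.size
        self.n_channels = self.train_samples[0].series.shape[1]
        self.n_timesteps = self.train_samples[0].series.shape[0]

    def fit(self) -> "CevvoResults":
        network = build_model(self.config, static_dim=self.static_dim,
                              n_channels=self.n_channels)
        history = train(network, self.train_samples, self.val_samples, self.config)
        return CevvoResults(model=self, network=network, history=history)


@dataclass
class CevvoResults:
    """Fitted classifier: trained network, history, prediction and summary."""

    model: CevvoClassifier
    network: CevvoNetwork
    history: dict = field(repr=False)

    def predict(self, samples: Sequence[Sample]) -> list[Prediction]:
        return predict(self.network, samples)

    def predict_scores(self, samples: Sequence[Sample]) -> np.ndarray:
        return np.array([p.score for p in self.predict(samples)])

    def summary(self) -> str:
        cfg = self.model.config
        m = self.model
        lines = [
            "CEVVO classifier results",
            "=" * 46,
            f"{'train samples':<28}{len(m.train_samples):>18}",
            f"{'validation samples':<28}"
            f"{len(m.val_samples) if m.val_samples else 0:>18}",
            f"{'time steps x channels':<28}"
            f"{f'{m.n_timesteps} x {m.n_channels}':>18}",
            f"{'flattened temporal input':<28}"
            f"{m.n_timesteps * m.n_channels:>18}",
            f"{'static input width':<28}{m.static_dim:>18}",
            f"{'static head widths':<28}{str(cfg.static_widths):>18}",
            f"{'conv filters / LSTM units':<28}"
            f"{f'{cfg.temporal_filters} / {cfg.lstm_units}':>18}",
            f"{'fusion width':<28}{self.network.fusion_width:>18}",
            f"{'epochs run (best)':<28}"
            f"{self.history['epochs_run']:>13} ({self.history['best_epoch']})",
            f"{'final train loss':<28}{self.history['train_loss'][-1]:>18.4f}",
        ]
        if self.history["val_loss"]:
            lines.append(
                f"{'best validation loss':<28}"
                f"{min(self.history['val_loss']):>18.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)


def flatten_features(samples: Sequence[Sample]) -> np.ndarray:
    """Concatenate flattened series (T*V) and the static vector per sample."""
    return np.stack([np.concatenate([s.series.ravel(), s.static_vec])
                     for s in samples])


@dataclass
class BaselineResults:
    """A fitted reference classifier with the sample-based prediction interface."""

    kind: str
    estimator: object

    def predict_scores(self, samples: Sequence[Sample]) -> np.ndarray:
        proba = self.estimator.predict_proba(flatten_features(samples))[:, 1]
        return np.clip(proba, _SCORE_EPS, 1.0 - _SCORE_EPS)

    def predict(self, samples: Sequence[Sample]) -> list[Prediction]:
        return [Prediction(patient_id=s.patient_id,
                           truncation_fraction=s.truncation_fraction,
                           score=float(p), label=s.label, end_day=s.end_day)
                for s, p in zip(samples, self.predict_scores(samples))]


def fit_baseline(kind: str, train_samples: Sequence[Sample], seed: int = 0,
                 ) -> BaselineResults:
    """Fit one of the reference classifiers on flattened temporal+static features."""
    if kind == "logistic_regression":
        est = LogisticRegression(max_iter=2000)
    elif kind == "naive_bayes":
        est = GaussianNB()
    elif kind == "dense_network":
        est = MLPClassifier(hidden_layer_sizes=(64, 32), max_iter=400,
                            random_state=seed)
    elif kind == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}; "
                         f"expected one of {BASELINE_KINDS}")
    Xf = flatten_features(train_samples)
    y = np.array([s.label for s in train_samples])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter at small n
        est.fit(Xf, y)
    return BaselineResults(kind=kind, estimator=est)
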