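"""Event-level signal-quality CNN.

A small 1-D CNN maps each 400-sample normalized event segment to the
probability that the event is a *false detection* (noise) rather than a true
heartbeat.  The architecture is three strided valid convolutions (16/32/64
filters, kernel 10, stride 2), average pooling (kernel 5, stride 2) after the
second and third convolutions, and fully connected layers of 40, 40, and 1
neurons with dropout 0.5/0.25 after the first two; the single output neuron
is sigmoid.  For a 400-sample input the temporal lengths through the network
are 196, 94, 45, 18, and 7.

Class imbalance between true beats (M0) and false detections (M1) is handled
with a weighted binary cross entropy,

    L = -(1/M) sum_i [ w1 y_i log(p_i) + w0 (1 - y_i) log(1 - p_i) ],

with inverse-frequency weights w_j = M / (2 M_j).  The decision threshold on
the sigmoid output is the value that maximizes the F1-score (false detection
as the positive class) on the validation split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .events import EventDataset

__all__ = [
    "QcModelConfig",
    "TrainConfig",
    "ClassWeights",
    "QcModel",
    "conv_output_length",
    "temporal_lengths",
    "layer_param_counts",
    "class_weights",
    "weighted_bce",
    "train_qc",
    "select_threshold",
    "classify_events",
    "f1_from_counts",
    "QcClassifier",
    "QcResults",
]

EPS = 1e-7  # prediction clipping so the cross entropy stays finite


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcModelConfig:
    """Architecture of the quality-control CNN (defaults are the shipped net)."""

    input_len: int = 400
    conv_layers: tuple[tuple[int, int, int], ...] = (
        (16, 10, 2), (32, 10, 2), (64, 10, 2))   # (filters, kernel, stride)
    pool_kernel: int = 5
    pool_stride: int = 2
    pool_after: tuple[int, ...] = (2, 3)          # 1-based conv indices
    fc_sizes: tuple[int, ...] = (40, 40, 1)
    dropout_rates: tuple[float, ...] = (0.5, 0.25)  # after FC-1 and FC-2
    l2_first_conv: float = 0.01


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 0.001
    patience: int = 0     # epochs the validation loss may exceed its best
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-frequency loss weights: w_j = M / (2 M_j)."""

    w0: float  # true beats
    w1: float  # false detections

    def __post_init__(self) -> None:
        if self.w0 <= 0 or self.w1 <= 0:
            raise ValueError("class weights must be positive")


# ---------------------------------------------------------------------------
# Architecture arithmetic
# ---------------------------------------------------------------------------

def conv_output_length(l_in: int, kernel: int, stride: int) -> int:
    """Output length of a valid (unpadded) strided convolution or pooling."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if l_in < kernel:
        raise ValueError(f"input length {l_in} shorter than kernel {kernel}")
    return (l_in - kernel) // stride + 1


def temporal_lengths(config: QcModelConfig = QcModelConfig()) -> list[int]:
    """Temporal lengths after each conv/pool stage (196, 94, 45, 18, 7 by default)."""
    lengths = []
    l = config.input_len
    for i, (_, k, s) in enumerate(config.conv_layers, start=1):
        l = conv_output_length(l, k, s)
        lengths.append(l)
        if i in config.pool_after:
            l = conv_output_length(l, config.pool_kernel, config.pool_stride)
            lengths.append(l)
    return lengths


def layer_param_counts(config: QcModelConfig = QcModelConfig()) -> list[tuple[str, int]]:
    """Trainable parameter count per layer, pooling/dropout counted as zero."""
    counts: list[tuple[str, int]] = []
    c_in = 1
    l = config.input_len
    for i, (filt, k, s) in enumerate(config.conv_layers, start=1):
        counts.append((f"conv{i}", filt * k * c_in + filt))
        l = conv_output_length(l, k, s)
        c_in = filt
        if i in config.pool_after:
            counts.append((f"pool{i}", 0))
            l = conv_output_length(l, config.pool_kernel, config.pool_stride)
    n_in = l * c_in
    for j, n_out in enumerate(config.fc_sizes, start=1):
        counts.append((f"fc{j}", n_in * n_out + n_out))
        if j <= len(config.dropout_rates):
            counts.append((f"dropout{j}", 0))
        n_in = n_out
    return counts


def _build_network(config: QcModelConfig, rng: np.random.Generator) -> _nn.Sequential:
    layers: list[_nn.Layer] = []
    c_in = 1
    for i, (filt, k, s) in enumerate(config.conv_layers, start=1):
        l2 = config.l2_first_conv if i == 1 else 0.0
        layers.append(_nn.Conv1D(c_in, filt, k, s, rng, l2=l2))
        layers.append(_nn.ReLU())
        if i in config.pool_after:
            layers.append(_nn.AvgPool1D(config.pool_kernel, config.pool_stride))
        c_in = filt
    layers.append(_nn.Flatten())
    n_in = temporal_lengths(config)[-1] * c_in
    for j, n_out in enumerate(config.fc_sizes, start=1):
        layers.append(_nn.Dense(n_in, n_out, rng))
        if j < len(config.fc_sizes):
            layers.append(_nn.ReLU())
            if j <= len(config.dropout_rates):
                layers.append(_nn.Dropout(config.dropout_rates[j - 1]))
        n_in = n_out
    return _nn.Sequential(layers)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def class_weights(m0: int, m1: int) -> ClassWeights:
    """w_j = (1/M_j)(M/2); satisfies M0*w0 + M1*w1 = M."""
    if m0 <= 0 or m1 <= 0:
        raise ValueError("both class counts must be positive")
    m = m0 + m1
    return ClassWeights(w0=m / (2.0 * m0), w1=m / (2.0 * m1))


def weighted_bce(y: np.ndarray, y_hat: np.ndarray,
                 weights: ClassWeights = ClassWeights(1.0, 1.0)) -> float:
    """Weighted binary cross entropy; predictions clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("labels and predictions must have equal length")
    p = np.clip(y_hat, EPS, 1.0 - EPS)
    terms = weights.w1 * y * np.log(p) + weights.w0 * (1 - y) * np.log(1 - p)
    return float(-np.mean(terms))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class QcModel:
    """Trained quality-control CNN: maps (n, 400) segments to P(false detection)."""

    def __init__(self, net: _nn.Sequential, config: QcModelConfig):
        self.net = net
        self.config = config

    def predict_proba(self, X: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        out = []
        for i in range(0, len(X), batch_size):
            z = self.net.forward(X[i:i + batch_size, :, None], training=False)
            out.append(_nn.sigmoid(z[:, 0]))
        return np.concatenate(out) if out else np.empty(0)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write parameters (.npz) and a YAML config echo next to it."""
        import yaml

        path = Path(path)
        state = self.net.get_state()
        np.savez(path, **{f"p{i}": p for i, p in enumerate(state)})
        cfg_path = path.with_suffix(".yaml")
        cfg_path.write_text(yaml.safe_dump(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "QcModel":
        import yaml

        path = Path(path)
        raw = yaml.safe_load(path.with_suffix(".yaml").read_text())
        for key in ("conv_layers", "pool_after", "fc_sizes", "dropout_rates"):
            raw[key] = tuple(tuple(v) if isinstance(v, list) else v
                             for v in raw[key])
        config = QcModelConfig(**raw)
        net = _build_network(config, np.random.default_rng(0))
        with np.load(path if path.suffix == ".npz"
                     else path.with_suffix(".npz")) as data:
            net.set_state([data[f"p{i}"] for i in range(len(data.files))])
        return cls(net, config)


def train_qc(
    dataset: EventDataset,
    mconfig: QcModelConfig = QcModelConfig(),
    tconfig: TrainConfig = TrainConfig(),
) -> tuple[QcModel, list[dict]]:
    """Train the CNN with early stopping on the validation loss.

    The loss is the weighted cross entropy with weights computed from the
    training split, plus the L2 penalty on the first convolutional layer.
    Validation loss is evaluated at the end of every epoch; when it exceeds
    its best value for more than ``patience`` consecutive epochs, training
    stops and the best-epoch parameters are restored.  Deterministic given
    ``tconfig.seed``.
    """
    X_tr, y_tr = dataset.subset("train")
    X_val, y_val = dataset.subset("validation")
    if len(y_tr) == 0 or len(y_val) == 0:
        raise ValueError("train and validation splits must be non-empty")
    w = class_weights(int((y_tr == 0).sum()), int((y_tr == 1).sum()))

    ss = np.random.SeedSequence(tconfig.seed)
    s_init, s_shuffle, s_dropout = ss.spawn(3)
    net = _build_network(mconfig, np.random.default_rng(s_init))
    shuffle_rng = np.random.default_rng(s_shuffle)
    dropout_rng = np.random.default_rng(s_dropout)
    opt = _nn.Adam(net, lr=tconfig.learning_rate)
    model = QcModel(net, mconfig)

    best_val = np.inf
    best_state = net.get_state()
    bad = 0
    history: list[dict] = []
    for epoch in range(1, tconfig.epochs + 1):
        perm = shuffle_rng.permutation(len(y_tr))
        batch_losses = []
        for i in range(0, len(perm), tconfig.batch_size):
            idx = perm[i:i + tconfig.batch_size]
            xb = X_tr[idx][:, :, None].astype(float)
            yb = y_tr[idx].astype(float)
            z = net.forward(xb, training=True, rng=dropout_rng)[:, 0]
            p = _nn.sigmoid(z)
            loss = weighted_bce(yb, p, w) + net.l2_penalty()
            batch_losses.append(loss)
            # d(loss)/dz for the weighted cross entropy through the sigmoid
            dz = (w.w1 * yb * (p - 1.0) + w.w0 * (1.0 - yb) * p) / len(yb)
            net.backward(dz[:, None])
            opt.step()
        val_loss = weighted_bce(y_val, model.predict_proba(X_val), w)
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(batch_losses)),
                        "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.get_state()
            bad = 0
        else:
            bad += 1
            if bad > tconfig.patience:
                break
    net.set_state(best_state)
    return model, history


# ---------------------------------------------------------------------------
# Threshold selection and classification
# ---------------------------------------------------------------------------

def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_threshold(probabilities: np.ndarray, labels: np.ndarray,
                     grid_step: float = 0.01) -> tuple[float, float]:
    """Smallest threshold in {0.01, ..., 0.99} maximizing validation F1.

    F1 treats false detections (y = 1) as the positive class.  Returns
    (threshold, F1 at threshold).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold selection needs both classes present")
    n_steps = int(round(1.0 / grid_step)) - 1
    grid = np.round(np.arange(1, n_steps + 1) * grid_step, 10)
    best_theta, best_f1 = grid[0], -1.0
    for theta in grid:
        pred = p > theta
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        f1 = f1_from_counts(tp, fp, fn)
        if f1 > best_f1:
            best_theta, best_f1 = float(theta), f1
    return best_theta, best_f1


def classify_events(model: QcModel, X: np.ndarray,
                    threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Label events: false detection iff P(false) > threshold (strict).

    Returns (labels in {0,1}, probabilities).
    """
    probs = model.predict_proba(X)
    return (probs > threshold).astype(np.int8), probs


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

@dataclass
class QcResults:
    """Fit results: trained model, operating threshold, and split metrics."""

    model: QcModel
    threshold: float
    validation_f1: float
    history: list[dict]
    split_metrics: dict[str, dict[str, float]]
    class_weights: ClassWeights

    def summary(self) -> str:
        lines = [
            "Quality-control CNN fit",
            "=" * 55,
            f"epochs run            : {len(self.history)}",
            f"best validation loss  : "
            f"{min(h['val_loss'] for h in self.history):.4f}",
            f"class weights (w0,w1) : "
            f"({self.class_weights.w0:.4f}, {self.class_weights.w1:.4f})",
            f"decision threshold    : {self.threshold:.2f} "
            f"(validation F1 = {self.validation_f1:.4f})",
            "-" * 55,
            f"{'split':<12}{'Se%':>8}{'Sp%':>8}{'Acc%':>8}{'F1%':>8}",
        ]
        for split, m in self.split_metrics.items():
            lines.append(f"{split:<12}{m['Se'] * 100:>8.1f}{m['Sp'] * 100:>8.1f}"
                         f"{m['Acc'] * 100:>8.1f}{m['F1'] * 100:>8.1f}")
        return "\n".join(lines)


class QcClassifier:
    """statsmodels-style wrapper: construct from an EventDataset, then fit()."""

    def __init__(self, dataset: EventDataset,
                 model_config: QcModelConfig = QcModelConfig(),
                 train_config: TrainConfig = TrainConfig()):
        self.dataset = dataset
        self.model_config = model_config
        self.train_config = train_config

    def fit(self) -> QcResults:
        model, history = train_qc(self.dataset, self.model_config,
                                  self.train_config)
        X_val, y_val = self.dataset.subset("validation")
        theta, f1 = select_threshold(model.predict_proba(X_val), y_val)

        y_tr = self.dataset.subset("train")[1]
        cw = class_weights(int((y_tr == 0).sum()), int((y_tr == 1).sum()))

        from .evaluation import confusion, metrics

        split_metrics = {}
        for split in ("validation", "test"):
            X_s, y_s = self.dataset.subset(split)
            if len(y_s) == 0:
                continue
            pred, _ = classify_events(model, X_s, theta)
            m = metrics(confusion(pred, y_s, positive=1))
            split_metrics[split] = {k: v for k, v in m.as_dict().items()
                                    if v is not None}
        return QcResults(model=model, threshold=theta, validation_f1=f1,
                         history=history, split_metrics=split_metrics,
                         class_weights=cw)
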