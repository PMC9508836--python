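"""The per-variant-type convolutional DNM classifier.

Architecture: nine 3x3 stride-1 same-padding convolutional layers with 96
filters and ReLU activations; after every third convolution, batch
normalization followed by a squeeze-and-excitation block; the head
concatenates global max pooling and global average pooling and feeds a
single sigmoid unit carrying an L1 penalty.  Three instances of this
network are trained — substitutions, insertions, deletions — because the
three variant classes have distinct visual signatures; the indel networks
warm-start from the trained substitution weights.

Training minimises binary cross-entropy with Adam (substitutions) or
AdamW (indels), an initial learning rate halved every 10 epochs, up to
100 epochs with early stopping after 40 epochs without validation
improvement, and returns the weights of the best-validation epoch.

A candidate is labelled de novo when the predicted DNM probability is
>= 0.5 (inclusive threshold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .candidates import VariantCandidate
from .encoder import IMAGE_CHANNELS, IMAGE_COLS, IMAGE_ROWS, EncodedVariantImage

__all__ = [
    "ModelConfig",
    "TrainingConfig",
    "SearchSpace",
    "ClassificationResult",
    "TrainingHistory",
    "build_network",
    "se_block",
    "learning_rate_at",
    "train",
    "hyperparameter_search",
    "predict",
    "predict_proba",
    "save_checkpoint",
    "load_checkpoint",
]

DNM_THRESHOLD = 0.5


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters fixing the network topology."""

    conv_layers: int = 9
    filters_per_layer: int = 96
    kernel: int = 3
    se_block_every: int = 3
    se_reduction_ratio: int = 16
    l1_coefficient: float = 1e-6
    input_shape: Tuple[int, int, int] = (IMAGE_ROWS, IMAGE_COLS, IMAGE_CHANNELS)

    def __post_init__(self) -> None:
        if self.conv_layers % self.se_block_every != 0:
            raise ValueError("conv_layers must be divisible by se_block_every")
        if self.filters_per_layer <= 0 or self.se_reduction_ratio <= 0:
            raise ValueError("filters and reduction ratio must be positive")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation schedule parameters."""

    max_epochs: int = 100
    early_stop_patience: int = 40
    optimizer: str = "adam"  # "adam" or "adamw"
    weight_decay: float = 0.0
    initial_learning_rate: float = 1e-3
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 10
    batch_size: int = 32
    rng_seed: int = 0
    init_weights: Optional[List[np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.initial_learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.optimizer not in ("adam", "adamw"):
            raise ValueError("optimizer must be adam or adamw")


@dataclass(frozen=True)
class SearchSpace:
    """Random-search bounds for hyperparameter optimisation."""

    filters: Tuple[int, ...] = (32, 64, 96, 128)
    batch_sizes: Tuple[int, ...] = (32, 64)
    l1_bounds: Tuple[float, float] = (1e-10, 0.1)
    learning_rate_bounds: Tuple[float, float] = (1e-8, 0.01)
    weight_decay_bounds: Tuple[float, float] = (1e-8, 0.01)

    def sample(self, rng: np.random.Generator,
               base_model: ModelConfig = ModelConfig(),
               base_training: TrainingConfig = TrainingConfig()
               ) -> Tuple[ModelConfig, TrainingConfig]:
        """Draw one configuration; continuous values are log-uniform."""

        def log_uniform(lo: float, hi: float) -> float:
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        model = replace(
            base_model,
            filters_per_layer=int(rng.choice(self.filters)),
            l1_coefficient=log_uniform(*self.l1_bounds),
        )
        training = replace(
            base_training,
            batch_size=int(rng.choice(self.batch_sizes)),
            initial_learning_rate=log_uniform(*self.learning_rate_bounds),
            weight_decay=log_uniform(*self.weight_decay_bounds),
        )
        return model, training


@dataclass(frozen=True)
class ClassificationResult:
    """Prediction for one candidate: DNM probability and thresholded label."""

    candidate: Optional[VariantCandidate]
    p_dnm: float
    model_used: str

    @property
    def label(self) -> str:
        return "DNM" if self.p_dnm >= DNM_THRESHOLD else "IV"


@dataclass
class TrainingHistory:
    """Per-epoch record of the schedule and losses."""

    epochs: List[dict] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def record(self, **kwargs) -> None:
        self.epochs.append(dict(**kwargs))


def build_network(config: ModelConfig = ModelConfig(), seed: int = 0) -> nn.Sequential:
    """Assemble the classifier; same seed -> identical initial weights."""
    rng = np.random.default_rng(seed)
    layers: List[nn.Layer] = []
    c_in = config.input_shape[2]
    for i in range(1, config.conv_layers + 1):
        layers.append(nn.Conv2d(c_in, config.filters_per_layer, config.kernel, rng))
        layers.append(nn.ReLU())
        c_in = config.filters_per_layer
        if i % config.se_block_every == 0:
            layers.append(nn.BatchNorm(c_in))
            layers.append(nn.SqueezeExcite(c_in, config.se_reduction_ratio, rng))
    layers.append(nn.GlobalPoolConcat())
    layers.append(nn.Dense(2 * c_in, 1, rng, l1=config.l1_coefficient))
    return nn.Sequential(layers)


def se_block(feature_maps: np.ndarray, reduction_ratio: int = 16,
             layer: Optional[nn.SqueezeExcite] = None,
             seed: int = 0) -> np.ndarray:
    """Apply a squeeze-and-excitation gate to NHWC feature maps.

    Provided as a standalone operation for inspection; ``layer`` may carry
    trained parameters, otherwise a freshly initialised block is used.
    """
    if layer is None:
        rng = np.random.default_rng(seed)
        layer = nn.SqueezeExcite(feature_maps.shape[3], reduction_ratio, rng)
    return layer.forward(feature_maps.astype(np.float32), train=False)


def learning_rate_at(epoch: int, config: TrainingConfig) -> float:
    """Stepwise-decayed learning rate for a 0-based epoch index.

    lr(e) = lr0 * decay^floor(e / every); with the defaults, epoch 25 of
    an initial 1e-3 run uses 2.5e-4 (two halvings).
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    steps = epoch // config.lr_decay_every
    return config.initial_learning_rate * config.lr_decay_factor ** steps


def _as_float_batch(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x, dtype=np.float32) / 255.0


def train(
    model: nn.Sequential,
    train_set: Tuple[np.ndarray, np.ndarray],
    val_set: Tuple[np.ndarray, np.ndarray],
    config: TrainingConfig = TrainingConfig(),
    augment_fn=None,
) -> Tuple[nn.Sequential, TrainingHistory]:
    """Train with the stepwise LR schedule, early stopping and best-epoch
    checkpointing; returns the model restored to its best-validation weights.

    ``train_set``/``val_set`` are (images NHWC uint8, binary labels).
    ``augment_fn(batch, rng) -> batch`` is applied to each training batch.
    Raises on empty datasets and aborts on non-finite loss.
    """
    x_train, y_train = train_set
    x_val, y_val = val_set
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty training or validation set")
    if config.init_weights is not None:
        model.set_weights(config.init_weights)

    rng = np.random.default_rng(config.rng_seed)
    decay = config.weight_decay if config.optimizer == "adamw" else 0.0
    optimizer = nn.Adam(model.params(), lr=config.initial_learning_rate,
                        weight_decay=decay)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()

    for epoch in range(config.max_epochs):
        lr = learning_rate_at(epoch, config)
        optimizer.lr = lr
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb = x_train[idx]
            if augment_fn is not None:
                xb = augment_fn(xb, rng)
            xb = _as_float_batch(xb)
            yb = y_train[idx]
            model.zero_grad()
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.bce_loss_and_grad(logits, yb)
            loss += model.l1_penalty()
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            model.backward(dlogits)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1

        val_loss, val_acc = evaluate_model(model, x_val, y_val,
                                           batch_size=config.batch_size)
        history.record(epoch=epoch, lr=lr,
                       train_loss=epoch_loss / max(1, n_batches),
                       val_loss=val_loss, val_accuracy=val_acc)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
        if epoch - history.best_epoch >= config.early_stop_patience:
            history.stopped_epoch = epoch
            break
    else:
        history.stopped_epoch = config.max_epochs - 1

    model.set_weights(best_weights)
    return model, history


def evaluate_model(model: nn.Sequential, x: np.ndarray, y: np.ndarray,
                   batch_size: int = 64) -> Tuple[float, float]:
    """Mean BCE loss and thresholded accuracy over a dataset."""
    total_loss = 0.0
    correct = 0
    for lo in range(0, len(x), batch_size):
        xb = _as_float_batch(x[lo:lo + batch_size])
        yb = y[lo:lo + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = nn.bce_loss_and_grad(logits, yb)
        total_loss += loss * len(yb)
        p = nn.sigmoid(logits[:, 0])
        correct += int(np.sum((p >= DNM_THRESHOLD) == (yb > 0.5)))
    return total_loss / len(x), correct / len(x)


def hyperparameter_search(
    space: SearchSpace,
    budget: int,
    train_set: Tuple[np.ndarray, np.ndarray],
    val_set: Tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    base_model: ModelConfig = ModelConfig(),
    base_training: TrainingConfig = TrainingConfig(),
) -> Tuple[ModelConfig, TrainingConfig, float]:
    """Seeded random search minimising validation cross-entropy.

    Draws ``budget`` configurations from ``space``, trains each briefly,
    and returns the (model config, training config, val loss) of the best.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    best: Optional[Tuple[ModelConfig, TrainingConfig, float]] = None
    for trial in range(budget):
        mcfg, tcfg = space.sample(rng, base_model, base_training)
        tcfg = replace(tcfg, rng_seed=int(rng.integers(2 ** 31)))
        model = build_network(mcfg, seed=int(rng.integers(2 ** 31)))
        model, history = train(model, train_set, val_set, tcfg)
        val_loss = min(e["val_loss"] for e in history.epochs)
        if best is None or val_loss < best[2]:
            best = (mcfg, tcfg, val_loss)
    assert best is not None
    return best


def predict_proba(model: nn.Sequential, image: EncodedVariantImage) -> float:
    x = _as_float_batch(image.tensor[None, ...])
    return float(model.predict_proba(x)[0])


def predict(
    model_bank: Dict[str, nn.Sequential],
    image: EncodedVariantImage,
    candidate: Optional[VariantCandidate] = None,
) -> ClassificationResult:
    """Classify one encoded candidate with the model for its variant type."""
    vtype = image.variant_type
    if vtype not in model_bank:
        raise KeyError(f"no model loaded for variant type {vtype!r}")
    p = predict_proba(model_bank[vtype], image)
    return ClassificationResult(candidate=candidate, p_dnm=p, model_used=vtype)


def save_checkpoint(model: nn.Sequential, config: ModelConfig, path) -> None:
    """Weights as .npz plus a JSON sidecar recording the architecture."""
    path = Path(path)
    weights = model.get_weights()
    np.savez(path, **{f"w{i}": w for i, w in enumerate(weights)})
    sidecar = dict(asdict(config))
    sidecar["n_arrays"] = len(weights)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path) -> Tuple[nn.Sequential, ModelConfig]:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    n = sidecar.pop("n_arrays")
    sidecar["input_shape"] = tuple(sidecar["input_shape"])
    config = ModelConfig(**sidecar)
    model = build_network(config, seed=0)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.set_weights([data[f"w{i}"] for i in range(n)])
    return model, config
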