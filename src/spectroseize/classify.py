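"""Classifier architectures, patient-level splits, balancing, training loop.

Five architectures are supported: three plain CNNs (6, 7 and 12 layers,
counting convolutional and dense layers) that are built as trainable
networks on the numpy engine, and the two standard residual networks
(ResNet18, ResNet50) represented structurally for exact trainable-parameter
accounting with the stock classification head replaced by a 2-unit dense
output. All layers are trainable; the 50-layer residual stack comes to
~23.5 million trainable parameters and the 6-layer CNN (at its full
224x224 input) to ~1.5 million.

Splits are always at the patient level: a random 72/18/23 train/validation/
test partition of 113 patients per fold, or, for the data-scaling design,
105 patients sorted into 5 equal bins by labeled-record count with nested
training sets of 10..80 patients drawn equally from every bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nn

ARCHITECTURE_IDS = ("cnn6", "cnn7", "cnn12", "resnet18", "resnet50")
N_CLASSES = 2


@dataclass(frozen=True)
class ArchitectureSpec:
    id: str
    input_size: tuple[int, int, int] = (224, 224, 3)

    def __post_init__(self):
        if self.id not in ARCHITECTURE_IDS:
            raise ValueError(f"unknown architecture '{self.id}'; expected {ARCHITECTURE_IDS}")


# ---------------------------------------------------------------------------
# architecture construction and parameter counting


_CNN_STACKS = {
    # (conv widths with '|' marking a 2x2 max-pool after the block, dense widths)
    "cnn6": ((32, 64, 128, 128), (50,)),
    "cnn7": ((32, 64, 128, 128, 256), (64,)),
    "cnn12": ((32, 32, 64, 64, 128, 128, 256, 256, 256, 256), (128,)),
}
#: cnn12 pools after every second conv; cnn6/cnn7 after every conv block
_CNN_POOL_EVERY = {"cnn6": 1, "cnn7": 1, "cnn12": 2}


def _cnn_layers(arch_id: str, input_size: tuple[int, int, int],
                rng: np.random.Generator) -> list[nn.Layer]:
    convs, denses = _CNN_STACKS[arch_id]
    pool_every = _CNN_POOL_EVERY[arch_id]
    h, w, c = input_size
    layers: list[nn.Layer] = []
    for i, width in enumerate(convs):
        layers += [nn.Conv3x3(c, width, rng), nn.ReLU()]
        c = width
        if (i + 1) % pool_every == 0:
            layers.append(nn.MaxPool2())
            h, w = h // 2, w // 2
            if h == 0 or w == 0:
                raise ValueError(f"input {input_size} too small for {arch_id}")
    layers.append(nn.Flatten())
    dim = h * w * c
    for width in denses:
        layers += [nn.Dense(dim, width, rng), nn.ReLU()]
        dim = width
    layers.append(nn.Dense(dim, N_CLASSES, rng))
    return layers


def _resnet_param_count(arch_id: str) -> int:
    """Exact trainable-parameter count of the standard residual stacks with
    a 2-unit dense head on the pooled final feature.

    Convolutions carry biases and batch-norm contributes its scale and shift
    (running statistics are not trainable and are excluded), matching the
    stock implementations the study fine-tuned.
    """

    def conv(k, cin, cout):
        return k * k * cin * cout + cout

    def bn(c):
        return 2 * c

    total = conv(7, 3, 64) + bn(64)
    if arch_id == "resnet50":
        stages = [((64, 64, 256), 3), ((128, 128, 512), 4),
                  ((256, 256, 1024), 6), ((512, 512, 2048), 3)]
        cin = 64
        for (f1, f3, fout), blocks in stages:
            for b in range(blocks):
                total += conv(1, cin, f1) + bn(f1) + conv(3, f1, f3) + bn(f3) \
                    + conv(1, f3, fout) + bn(fout)
                if b == 0:
                    total += conv(1, cin, fout) + bn(fout)
                cin = fout
        head_in = 2048
    else:  # resnet18
        cin = 64
        for f, blocks in [(64, 2), (128, 2), (256, 2), (512, 2)]:
            for b in range(blocks):
                total += conv(3, cin, f) + bn(f) + conv(3, f, f) + bn(f)
                if b == 0 and f != cin:
                    total += conv(1, cin, f) + bn(f)
                cin = f
        head_in = 512
    return total + head_in * N_CLASSES + N_CLASSES


def cnn_param_count(arch_id: str, input_size: tuple[int, int, int] = (224, 224, 3)) -> int:
    """Closed-form trainable-parameter count for the plain CNN stacks."""
    convs, denses = _CNN_STACKS[arch_id]
    pool_every = _CNN_POOL_EVERY[arch_id]
    h, w, c = input_size
    total = 0
    for i, width in enumerate(convs):
        total += 3 * 3 * c * width + width
        c = width
        if (i + 1) % pool_every == 0:
            h, w = h // 2, w // 2
    dim = h * w * c
    for width in denses:
        total += dim * width + width
        dim = width
    return total + dim * N_CLASSES + N_CLASSES


class CountOnlyModel:
    """Structural stand-in for the residual architectures.

    Exposes the exact trainable-parameter count and the 2-unit output
    contract; the forward/training pass of the residual stacks is outside
    this package's desk-scale scope.
    """

    def __init__(self, spec: ArchitectureSpec):
        self.spec = spec
        self.n_params = _resnet_param_count(spec.id)
        self.output_units = N_CLASSES

    def forward(self, x):  # pragma: no cover - contract only
        raise NotImplementedError(
            f"{self.spec.id} is represented structurally for parameter "
            "accounting; training it is out of scope")


class CnnModel(nn.Sequential):
    """A trainable plain-CNN classifier."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC00]))
        super().__init__(_cnn_layers(spec.id, spec.input_size, rng))
        self.spec = spec
        self.output_units = N_CLASSES


def build_model(spec: ArchitectureSpec, seed: int = 0):
    """Construct a model for an architecture spec.

    Plain CNNs come back as trainable networks; residual architectures as
    structural models exposing ``n_params`` (exact, batch-norm running
    statistics excluded) and the 2-way output contract.
    """
    if spec.id in _CNN_STACKS:
        return CnnModel(spec, seed)
    return CountOnlyModel(spec)


def trainable_parameter_count(arch_id: str,
                              input_size: tuple[int, int, int] = (224, 224, 3)) -> int:
    spec = ArchitectureSpec(arch_id, input_size)
    return build_model(spec).n_params


# ---------------------------------------------------------------------------
# patient-level splits


@dataclass(frozen=True)
class SplitPlan:
    """One leakage-free patient partition."""

    fold_id: int
    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...] = ()

    def __post_init__(self):
        verify_disjoint(self)


def verify_disjoint(plan: "SplitPlan") -> None:
    """Leakage guard: train/validation/test must be pairwise patient-disjoint."""
    t, v, s = set(plan.train), set(plan.validation), set(plan.test)
    overlap = (t & v) | (t & s) | (v & s)
    if overlap:
        raise ValueError(f"patient leakage across splits: {sorted(overlap)[:5]}")


def make_folds(patients: Sequence[str], n_folds: int = 5,
               fractions: tuple[float, float] = (0.64, 0.16),
               seed: int = 0) -> list[SplitPlan]:
    """Independent random train/validation/test partitions by patient.

    With 113 patients and the default fractions each fold is a 72/18/23
    partition; the test set is the remainder after the train and validation
    fractions are rounded to whole patients.
    """
    ids = [str(p) for p in patients]
    n = len(ids)
    n_train = round(fractions[0] * n)
    n_val = round(fractions[1] * n)
    if n_train < 1 or n_val < 1 or n_train + n_val >= n:
        raise ValueError(f"{n} patients cannot support fractions {fractions}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF01D]))
    plans = []
    for fold in range(n_folds):
        order = [ids[i] for i in rng.permutation(n)]
        plans.append(SplitPlan(
            fold_id=fold,
            train=tuple(order[:n_train]),
            validation=tuple(order[n_train:n_train + n_val]),
            test=tuple(order[n_train + n_val:]),
        ))
    return plans


N_BINS = 5


def assign_bins(patients_with_counts: Sequence[tuple[str, int]]) -> list[list[str]]:
    """Sort patients by labeled-record count and cut into 5 equal bins,
    bin 0 holding the fewest-record patients."""
    n = len(patients_with_counts)
    if n % N_BINS != 0:
        raise ValueError(f"{n} patients not divisible into {N_BINS} equal bins")
    per = n // N_BINS
    ordered = sorted(patients_with_counts, key=lambda pc: (pc[1], pc[0]))
    return [[p for p, _ in ordered[i * per:(i + 1) * per]] for i in range(N_BINS)]


def validation_size(n_train_patients: int) -> int:
    """The greater of five patients or 20% of the training-set patient count."""
    return max(5, math.ceil(0.2 * n_train_patients))


def make_bin_splits(patients_with_counts: Sequence[tuple[str, int]],
                    sizes: Sequence[int] = tuple(range(10, 81, 10)),
                    seed: int = 0) -> list[SplitPlan]:
    """Nested training sets drawn equally from the 5 record-count bins.

    The size-``s`` training set takes ``s/5`` patients from each bin; larger
    sets extend smaller ones (nestedness). Each size's validation set is
    drawn from the remaining patients, spread as evenly as possible across
    bins, with ``max(5, ceil(0.2 s))`` patients.
    """
    bins = assign_bins(patients_with_counts)
    per_bin = len(bins[0])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB145]))
    orders = [[b[i] for i in rng.permutation(per_bin)] for b in bins]
    plans = []
    for fold, s in enumerate(sizes):
        if s % N_BINS != 0:
            raise ValueError(f"training size {s} not divisible by {N_BINS}")
        k = s // N_BINS
        if k > per_bin:
            raise ValueError(f"training size {s} exceeds bin capacity {per_bin * N_BINS}")
        train = tuple(p for order in orders for p in order[:k])
        n_val = validation_size(s)
        base, extra = divmod(n_val, N_BINS)
        val: list[str] = []
        for b, order in enumerate(orders):
            take = base + (1 if b < extra else 0)
            avail = order[k:]
            if take > len(avail):
                raise ValueError(f"bin {b} cannot supply {take} validation patients")
            val.extend(avail[:take])
        plans.append(SplitPlan(fold_id=fold, train=train, validation=tuple(val)))
    return plans


def balance_training(examples_by_class: dict[str, list],
                     rng: np.random.Generator) -> dict[str, list]:
    """Randomly downsample the majority class to the minority count.

    Applied to the training split only; validation and test keep their
    natural class distribution.
    """
    for cls, items in examples_by_class.items():
        if not items:
            raise ValueError(f"class '{cls}' has no training examples")
    n_min = min(len(v) for v in examples_by_class.values())
    out = {}
    for cls, items in examples_by_class.items():
        if len(items) > n_min:
            idx = rng.choice(len(items), size=n_min, replace=False)
            out[cls] = [items[i] for i in sorted(idx)]
        else:
            out[cls] = list(items)
    return out


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults mirror the study protocol: batch 32, Nadam, at most 70 epochs,
    zero learning-rate decay, stop when validation accuracy has not improved
    on its best by at least 0.1 percentage points over 10 consecutive
    epochs, and keep the weights from the best-validation epoch. The
    learning rate defaults to 1e-6 for the plain CNNs and 1e-7 for the
    residual nets when left unset.
    """

    learning_rate: Optional[float] = None
    batch_size: int = 32
    optimizer: str = "nadam"
    max_epochs: int = 70
    early_stop_min_improvement: float = 0.1  # percentage points of val accuracy
    early_stop_window: int = 10  # consecutive epochs
    seed: int = 0

    def __post_init__(self):
        if self.optimizer not in nn.OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {list(nn.OPTIMIZERS)}")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be positive")
        if self.early_stop_window > self.max_epochs:
            raise ValueError("early-stop window cannot exceed max_epochs")

    def resolve_lr(self, arch_id: str) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-7 if arch_id.startswith("resnet") else 1e-6


DEFAULT_LEARNING_RATES = {"cnn6": 1e-6, "cnn7": 1e-6, "cnn12": 1e-6,
                          "resnet18": 1e-7, "resnet50": 1e-7}


class EarlyStopper:
    """Stop when no epoch in the trailing window improved the best
    validation accuracy by at least ``min_improvement`` percentage points."""

    def __init__(self, min_improvement: float = 0.1, window: int = 10):
        self.min_improvement = min_improvement
        self.window = window
        self.best = -np.inf
        self.best_epoch: Optional[int] = None
        self._last_improvement = 0

    def update(self, epoch: int, val_accuracy_pct: float) -> bool:
        """Record epoch (1-based) accuracy in percent; True means stop now."""
        if val_accuracy_pct >= self.best + self.min_improvement or self.best == -np.inf:
            self._last_improvement = epoch
        if val_accuracy_pct > self.best:
            self.best = val_accuracy_pct
            self.best_epoch = epoch
        return epoch - self._last_improvement >= self.window


class TrainingDiverged(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"loss became non-finite at epoch {epoch}")
        self.epoch = epoch


def stopping_epoch(val_accuracies_pct: Sequence[float],
                   min_improvement: float = 0.1, window: int = 10,
                   max_epochs: int = 70) -> int:
    """Epoch (1-based) at which the early-stopping rule halts a run with the
    given per-epoch validation accuracies; ``max_epochs`` if it never fires."""
    stopper = EarlyStopper(min_improvement, window)
    for e, acc in enumerate(val_accuracies_pct[:max_epochs], start=1):
        if stopper.update(e, acc):
            return e
    return min(len(val_accuracies_pct), max_epochs)


def train(model: CnnModel, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray,
          config: TrainConfig = TrainConfig()) -> pd.DataFrame:
    """Train a CNN with minibatch Nadam/Adam and the early-stopping protocol.

    ``x_*`` are NHWC image batches in [-1, 1]; ``y_*`` integer classes
    (0 = nsz, 1 = sz). The model is left holding the weights of the epoch
    with the highest validation accuracy. Returns the per-epoch history
    (epoch, train_loss, val_accuracy_pct).
    """
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x7247]))
    lr = config.resolve_lr(model.spec.id)
    opt = nn.OPTIMIZERS[config.optimizer](model.parameters, lr)
    stopper = EarlyStopper(config.early_stop_min_improvement, config.early_stop_window)
    best_weights = model.get_weights()
    history = []
    n = x_train.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            loss, _ = model.loss_and_grad(x_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(epoch)
            opt.step(model.gradients)
            losses.append(loss)
        proba = model.predict_proba(x_val)
        val_acc = 100.0 * float((proba.argmax(axis=1) == y_val).mean())
        prev_best = stopper.best
        stop = stopper.update(epoch, val_acc)
        if val_acc > prev_best:
            best_weights = model.get_weights()
        history.append((epoch, float(np.mean(losses)), val_acc))
        if stop:
            break
    model.set_weights(best_weights)
    return pd.DataFrame(history, columns=["epoch", "train_loss", "val_accuracy_pct"])
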