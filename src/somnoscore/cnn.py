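"""Class-specific CNN feature extractors.

Each extractor is a small convolutional network mapping one 30-s raw-EEG
epoch (1 x 3000 samples at 100 Hz) to a softmax over the five stages:

    conv(10 filters, 1x55) -> ReLU -> BN -> maxpool(1x16)
    -> conv(5 filters, 1x25) -> ReLU -> BN -> maxpool(1x16)
    -> flatten(55) -> FC(10) -> ReLU -> FC(5) -> softmax

Fifteen such models (3 epoch-shift views x 5 target stages) share this
architecture but differ in the class-weighted cross-entropy used to train
them.  For a model targeting stage c the weights are w_i = 0.5 / p_i with
p_c = N_c/N and p_{i!=c} = (N-N_c)/N, so the target stage and its complement
carry equal total importance (w_i * p_i = 0.5 for every i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .manipulation import EpochPairDataset, shuffle_split
from .stages import SCOREABLE_STAGES, StageLabel

N_CLASSES = 5
EPS_LOG = 1e-12  # probability floor inside ln


@dataclass
class CNNArchitecture:
    """Layer hyperparameters; defaults are the developed configuration."""

    input_length: int = 3000
    conv1_filters: int = 10
    conv1_kernel: int = 55
    pool1: int = 16
    conv2_filters: int = 5
    conv2_kernel: int = 25
    pool2: int = 16
    fc1: int = 10
    fc2: int = N_CLASSES


@dataclass
class ClassWeights:
    """Per-stage loss weights for one class-specific model."""

    target_class: StageLabel
    w: np.ndarray  # (5,) positive weights, canonical stage order
    p: np.ndarray  # (5,) proportions used to derive w
    class_count: int
    total: int

    @staticmethod
    def uniform() -> "ClassWeights":
        """All-ones weights (plain cross-entropy; the class-agnostic case)."""
        return ClassWeights(target_class=StageLabel.W,
                            w=np.ones(N_CLASSES), p=np.full(N_CLASSES, 0.5),
                            class_count=0, total=0)


def compute_class_weights(stage_counts: dict[StageLabel, int],
                          target: StageLabel) -> ClassWeights:
    """Loss weights for the model targeting ``target``.

    Every stage i receives w_i = 0.5/p_i where p_i is the target-stage
    proportion for i = target and the complement proportion otherwise.
    Requires 0 < N_target < N.
    """
    total = sum(stage_counts.get(s, 0) for s in SCOREABLE_STAGES)
    n_c = stage_counts.get(target, 0)
    if total <= 0:
        raise ValueError("no scoreable epochs")
    if n_c == 0 or n_c == total:
        raise ValueError(
            f"target stage {target.name} has degenerate proportion "
            f"{n_c}/{total}; weights undefined")
    p = np.empty(N_CLASSES)
    for i, stage in enumerate(SCOREABLE_STAGES):
        p[i] = n_c / total if stage is target else (total - n_c) / total
    return ClassWeights(target_class=target, w=0.5 / p, p=p,
                        class_count=n_c, total=total)


def weighted_cross_entropy(predicted: np.ndarray, targets_onehot: np.ndarray,
                           weights: ClassWeights | np.ndarray) -> float:
    """Stage-weighted cross-entropy: -(1/N) sum_n sum_i w_i Y_ni ln Yhat_ni.

    ``predicted`` rows are probabilities; they are clipped below at 1e-12
    before the natural log.
    """
    predicted = np.asarray(predicted, dtype=float)
    targets_onehot = np.asarray(targets_onehot, dtype=float)
    if predicted.shape != targets_onehot.shape:
        raise ValueError("predicted and targets must share a shape")
    w = weights.w if isinstance(weights, ClassWeights) else np.asarray(weights)
    logp = np.log(np.clip(predicted, EPS_LOG, None))
    return float(-(targets_onehot * w[None, :] * logp).sum() / predicted.shape[0])


@dataclass
class CNNTrainingConfig:
    """CNN training protocol: Adam(1e-3), batch 64 epochs, validation on the
    full held-out 30% every 150 iterations, patience 10 validations, at most
    ``max_training_epochs`` passes over the training set."""

    batch_size: int = 64
    learning_rate: float = 1e-3
    validation_interval: int = 150
    patience: int = 10
    max_training_epochs: int = 1000
    train_fraction: float = 0.7
    seed: int = 0
    return_best: bool = True  # best-validation checkpoint (vs last iteration)


class SleepStageCNN:
    """One class-specific feature extractor (architecture above)."""

    def __init__(self, arch: CNNArchitecture = CNNArchitecture(), seed: int = 0,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        a = arch
        self.dtype = dtype
        L1 = a.input_length // a.pool1
        L2 = L1 // a.pool2
        self.flat_dim = a.conv2_filters * L2
        self.arch = arch
        self.net = nn.Sequential([
            nn.Conv1d(1, a.conv1_filters, a.conv1_kernel, rng, dtype),
            nn.ReLU(),
            nn.BatchNorm1d(a.conv1_filters, dtype=dtype),
            nn.MaxPool1d(a.pool1),
            nn.Conv1d(a.conv1_filters, a.conv2_filters, a.conv2_kernel, rng, dtype),
            nn.ReLU(),
            nn.BatchNorm1d(a.conv2_filters, dtype=dtype),
            nn.MaxPool1d(a.pool2),
            nn.Flatten(),
            nn.Dense(self.flat_dim, a.fc1, rng, dtype),
            nn.ReLU(),
            nn.Dense(a.fc1, a.fc2, rng, dtype),
        ])

    # -- forward passes ----------------------------------------------------
    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, input_length) -> (N, 5) pre-softmax scores."""
        x = np.asarray(x, dtype=self.dtype)
        return self.net.forward(x[:, None, :], train=train)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = np.empty((x.shape[0], N_CLASSES))  # float64 probabilities
        for lo in range(0, x.shape[0], batch_size):
            out[lo:lo + batch_size] = nn.softmax(
                self.logits(x[lo:lo + batch_size]), axis=1)
        return out

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogits)

    # -- parameter bookkeeping ----------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return self.net.params()

    def gradients(self) -> list[np.ndarray]:
        return self.net.grads()

    def count_trainable_parameters(self) -> int:
        """Kernels, biases, BN scale/offset, FC weights/biases; running
        statistics excluded."""
        return self.net.n_params()

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.parameters()]
        for lay in self.net.layers:
            if isinstance(lay, nn.BatchNorm1d):
                state.append(lay.running_mean.copy())
                state.append(lay.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        n = len(self.parameters())
        for p, s in zip(self.parameters(), state[:n]):
            p[...] = s
        rest = iter(state[n:])
        for lay in self.net.layers:
            if isinstance(lay, nn.BatchNorm1d):
                lay.running_mean[...] = next(rest)
                lay.running_var[...] = next(rest)


def build_cnn(arch: CNNArchitecture = CNNArchitecture(),
              seed: int = 0) -> SleepStageCNN:
    return SleepStageCNN(arch, seed)


def count_trainable_parameters(model) -> int:
    """Trainable parameter count of a CNN, BiLSTM head, or ensemble part."""
    if hasattr(model, "count_trainable_parameters"):
        return model.count_trainable_parameters()
    if hasattr(model, "n_params"):
        return model.n_params()
    raise TypeError(f"cannot count parameters of {type(model)!r}")


@dataclass
class TrainedCNN:
    """A trained feature extractor plus its training history and identity."""

    model: SleepStageCNN
    weights: ClassWeights
    history: list[dict] = field(default_factory=list)
    set_id: str = ""
    target_class: str = ""
    seed: int = 0

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(x)


def _onehot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((y.size, N_CLASSES))
    out[np.arange(y.size), y] = 1.0
    return out


def train_cnn(pairs: EpochPairDataset, weights: ClassWeights,
              config: CNNTrainingConfig = CNNTrainingConfig(),
              arch: CNNArchitecture = CNNArchitecture(),
              set_id: str = "", verbose: bool = False) -> TrainedCNN:
    """Train one class-specific CNN with the weighted cross-entropy.

    The pair set is epoch-wise shuffled into 70/30 train/validation; Adam on
    batches of 64; validation loss on the full validation split every
    ``validation_interval`` iterations; stops after ``patience`` consecutive
    non-improving validations (strict improvement, min-delta 0) or after the
    pass cap.  Returns the best-validation checkpoint by default.
    """
    train, val = shuffle_split(pairs, config.train_fraction, seed=config.seed)
    if len(train) == 0:
        raise ValueError("empty training split")
    model = SleepStageCNN(arch, seed=config.seed)
    opt = nn.Adam(model.parameters(), model.gradients(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    Xtr = train.signals
    ytr = train.target_indices()
    Xval = val.signals
    Yval = _onehot(val.target_indices())
    w = weights.w

    best_loss = np.inf
    best_state = model.get_state()
    bad = 0
    it = 0
    history: list[dict] = []
    stop = False

    def validate() -> float:
        p = model.predict_proba(Xval)
        return weighted_cross_entropy(p, Yval, w)

    for epoch_pass in range(config.max_training_epochs):
        order = rng.permutation(len(train))
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb = Xtr[idx]
            yb = ytr[idx]
            logits = model.logits(xb, train=True)
            p = nn.softmax(logits, axis=1)
            Y = _onehot(yb)
            if not np.isfinite(p).all():
                raise FloatingPointError(
                    f"NaN/inf in CNN forward at iteration {it}")
            # d/dlogits of -(1/N) sum w_y ln p_y  =  (1/N) w_y (p - Y)
            dlogits = (w[yb][:, None] * (p - Y)) / xb.shape[0]
            model.backward(dlogits)
            opt.step()
            it += 1
            if it % config.validation_interval == 0:
                vloss = validate()
                tloss = weighted_cross_entropy(p, Y, w)
                history.append({"iteration": it, "train_loss": tloss,
                                "val_loss": vloss})
                if verbose:
                    print(f"  it {it}: train {tloss:.4f} val {vloss:.4f}")
                if vloss < best_loss:
                    best_loss = vloss
                    best_state = model.get_state()
                    bad = 0
                else:
                    bad += 1
                    if bad >= config.patience:
                        stop = True
                        break
        if stop:
            break

    # always run at least one validation so the history is non-empty
    if not history:
        vloss = validate()
        history.append({"iteration": it, "train_loss": float("nan"),
                        "val_loss": vloss})
        if vloss < best_loss:
            best_loss = vloss
            best_state = model.get_state()

    if config.return_best:
        model.set_state(best_state)
    return TrainedCNN(model=model, weights=weights, history=history,
                      set_id=set_id, target_class=weights.target_class.name,
                      seed=config.seed)
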