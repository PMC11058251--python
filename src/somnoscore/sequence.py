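"""Feature-sequence assembly and the BiLSTM many-to-many stage classifier.

Each record's epochs are pushed through the trained CNN ensemble: for every
included manipulation set the record is shifted accordingly and fed to that
set's five class-specific models.  In ``full`` mode every model contributes
its whole 5-way softmax (25 features per set; 75 in the developed three-set
configuration); ``condensed`` mode keeps only each model's target-class
probability (5 per set).  Feature ordering is set-major in the order
previous, current, next and class-minor in the order W, N1, N2, N3, REM, and
is serialized with trained models.

The BiLSTM (128 hidden units per direction, 5-way FC head) is trained
many-to-many over whole-record sequences with unweighted cross-entropy;
movement/unscored epochs keep their position, are relabeled W during
training, and are masked out of evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .cnn import N_CLASSES, TrainedCNN
from .io import EpochedRecord
from .manipulation import SET_ORDER, ManipulationSet, shift_sequence
from .stages import SCOREABLE_STAGES, StageLabel


@dataclass
class ModelRegistry:
    """Trained CNNs keyed by (manipulation set, target stage)."""

    models: dict[tuple[ManipulationSet, StageLabel], TrainedCNN] = field(
        default_factory=dict)

    def __len__(self) -> int:
        return len(self.models)

    def sets(self) -> list[ManipulationSet]:
        present = {k[0] for k in self.models}
        return [s for s in SET_ORDER if s in present]

    def get(self, set_id: ManipulationSet, target: StageLabel) -> TrainedCNN:
        try:
            return self.models[(set_id, target)]
        except KeyError:
            raise KeyError(
                f"registry has no CNN for ({set_id.name}, {target.name})") from None

    def feature_ordering(self, combo: list[ManipulationSet] | None = None,
                         mode: str = "full") -> list[str]:
        """Stable, self-describing feature-column names."""
        combo = self.sets() if combo is None else [
            s for s in SET_ORDER if s in combo]
        names = []
        for s in combo:
            for target in SCOREABLE_STAGES:
                if mode == "full":
                    names.extend(f"{s.name}:{target.name}:p{out.name}"
                                 for out in SCOREABLE_STAGES)
                else:
                    names.append(f"{s.name}:{target.name}:p{target.name}")
        return names


@dataclass
class FeatureSequence:
    """Per-record CNN-output features with training labels and eval mask.

    ``labels`` have MOVEMENT/UNKNOWN already relabeled W (sequence training
    needs a complete sequence); ``eval_mask`` is False at those positions.
    """

    features: np.ndarray          # (n_epochs, d)
    labels: np.ndarray            # (n_epochs,) int indices into SCOREABLE_STAGES
    eval_mask: np.ndarray         # (n_epochs,) bool
    record_id: str
    subject_id: str = ""

    @property
    def n_epochs(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]


def extract_feature_sequence(registry: ModelRegistry, rec: EpochedRecord,
                             combo: list[ManipulationSet] | None = None,
                             mode: str = "full") -> FeatureSequence:
    """Run one record through the ensemble, keeping the original epoch order."""
    if mode not in ("full", "condensed"):
        raise ValueError("mode must be 'full' or 'condensed'")
    combo = registry.sets() if combo is None else [
        s for s in SET_ORDER if s in combo]
    if not combo:
        raise ValueError("empty manipulation-set combination")
    blocks = []
    for set_id in combo:
        shifted = shift_sequence(rec.epochs, set_id)
        for target in SCOREABLE_STAGES:
            probs = registry.get(set_id, target).predict_proba(shifted)
            blocks.append(probs if mode == "full"
                          else probs[:, [target.value]])
    feats = np.concatenate(blocks, axis=1)
    labels = np.array(
        [(lab.value if lab.is_scoreable else StageLabel.W.value)
         for lab in rec.labels], dtype=np.int64)
    return FeatureSequence(features=feats, labels=labels,
                           eval_mask=rec.included.copy(),
                           record_id=rec.record_id, subject_id=rec.subject_id)


@dataclass
class BiLSTMConfig:
    """BiLSTM training protocol: Adam(0.01), batches of 4 record sequences,
    validation every 10 iterations, patience 10, record-wise 90/10 split."""

    hidden_units: int = 128
    batch_size: int = 4
    learning_rate: float = 0.01
    validation_interval: int = 10
    patience: int = 10
    max_training_epochs: int = 1000
    train_fraction: float = 0.9
    seed: int = 0
    return_best: bool = True


class SequenceClassifier:
    """BiLSTM(128) -> FC(5) -> softmax, one stage decision per epoch."""

    def __init__(self, input_dim: int, hidden_units: int = 128, seed: int = 0,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.dtype = dtype
        self.bilstm = nn.BiLSTM(input_dim, hidden_units, rng, dtype)
        self.head = nn.Dense(2 * hidden_units, N_CLASSES, rng, dtype)
        self.feature_names: list[str] = []

    def parameters(self):
        return self.bilstm.params() + self.head.params()

    def gradients(self):
        return self.bilstm.grads() + self.head.grads()

    def count_trainable_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def logits(self, x: np.ndarray, lengths: np.ndarray | None = None,
               train: bool = False) -> np.ndarray:
        """x: (N, T, d) padded batch -> (N, T, 5)."""
        x = np.asarray(x, dtype=self.dtype)
        h = self.bilstm.forward(x, train=train, lengths=lengths)
        N, T, H2 = h.shape
        self._h_shape = (N, T, H2)
        return self.head.forward(h.reshape(N * T, H2)).reshape(N, T, N_CLASSES)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        N, T, H2 = self._h_shape
        dh = self.head.backward(dlogits.reshape(N * T, N_CLASSES)).reshape(N, T, H2)
        return self.bilstm.backward(dh)

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s


@dataclass
class TrainedSequenceModel:
    model: SequenceClassifier
    history: list[dict] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    seed: int = 0


def _pad_batch(seqs: list[FeatureSequence]
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pad to the longest sequence; returns (x, y, valid, lengths)."""
    N = len(seqs)
    T = max(s.n_epochs for s in seqs)
    d = seqs[0].d
    x = np.zeros((N, T, d))
    y = np.zeros((N, T), dtype=np.int64)
    valid = np.zeros((N, T), dtype=bool)
    lengths = np.array([s.n_epochs for s in seqs])
    for n, s in enumerate(seqs):
        x[n, :s.n_epochs] = s.features
        y[n, :s.n_epochs] = s.labels
        valid[n, :s.n_epochs] = True
    return x, y, valid, lengths


def _masked_ce_and_grad(logits: np.ndarray, y: np.ndarray, valid: np.ndarray
                        ) -> tuple[float, np.ndarray]:
    """Mean unweighted CE over valid epochs; padded positions get zero grad."""
    p = nn.softmax(logits, axis=2)
    n_valid = int(valid.sum())
    idx = np.nonzero(valid)
    logp = np.log(np.clip(p[idx[0], idx[1], y[idx]], 1e-12, None))
    loss = float(-logp.sum() / n_valid)
    dlogits = np.zeros_like(logits)
    Y = np.zeros_like(p)
    Y[idx[0], idx[1], y[idx]] = 1.0
    dlogits[idx] = (p[idx] - Y[idx]) / n_valid
    return loss, dlogits


def train_bilstm(sequences: list[FeatureSequence],
                 config: BiLSTMConfig = BiLSTMConfig(),
                 verbose: bool = False) -> TrainedSequenceModel:
    """Train the sequence classifier on whole-record feature sequences.

    Record-wise 90/10 split (at least one validation record); batches of 4
    variable-length sequences, padded with the padding masked out of the
    loss; relabeled-W epochs participate in training.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 records to train the BiLSTM")
    d = sequences[0].d
    if any(s.d != d for s in sequences):
        raise ValueError("inconsistent feature dimensionality across records")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(sequences))
    n_train = int(round(config.train_fraction * len(sequences)))
    n_train = min(max(n_train, 1), len(sequences) - 1)
    train = [sequences[i] for i in order[:n_train]]
    val = [sequences[i] for i in order[n_train:]]

    model = SequenceClassifier(d, config.hidden_units, seed=config.seed)
    opt = nn.Adam(model.parameters(), model.gradients(), lr=config.learning_rate)

    def validate() -> float:
        total, n = 0.0, 0
        for s in val:
            x, y, valid, lengths = _pad_batch([s])
            logits = model.logits(x, lengths)
            loss, _ = _masked_ce_and_grad(logits, y, valid)
            total += loss * s.n_epochs
            n += s.n_epochs
        return total / n

    best_loss = np.inf
    best_state = model.get_state()
    bad = 0
    it = 0
    history: list[dict] = []
    stop = False
    for epoch_pass in range(config.max_training_epochs):
        perm = rng.permutation(len(train))
        for lo in range(0, len(perm), config.batch_size):
            batch = [train[i] for i in perm[lo:lo + config.batch_size]]
            x, y, valid, lengths = _pad_batch(batch)
            logits = model.logits(x, lengths, train=True)
            loss, dlogits = _masked_ce_and_grad(logits, y, valid)
            if not np.isfinite(loss):
                raise FloatingPointError(f"NaN loss at iteration {it}")
            model.backward(dlogits)
            opt.step()
            it += 1
            if it % config.validation_interval == 0:
                vloss = validate()
                history.append({"iteration": it, "train_loss": loss,
                                "val_loss": vloss})
                if verbose:
                    print(f"  it {it}: train {loss:.4f} val {vloss:.4f}")
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
    if not history:
        history.append({"iteration": it, "train_loss": float("nan"),
                        "val_loss": validate()})
        best_state = model.get_state()
    if config.return_best:
        model.set_state(best_state)
    return TrainedSequenceModel(model=model, history=history, seed=config.seed)


def predict_sequence(trained: TrainedSequenceModel | SequenceClassifier,
                     feats: FeatureSequence) -> list[StageLabel]:
    """One stage per epoch; ties broken toward the lower stage index."""
    model = trained.model if isinstance(trained, TrainedSequenceModel) else trained
    if feats.d != model.input_dim:
        raise ValueError(
            f"feature dimension {feats.d} != model input {model.input_dim}")
    x = feats.features[None, :, :]
    logits = model.logits(x)[0]
    # np.argmax returns the first (lowest) index on exact ties
    pred = np.argmax(nn.softmax(logits, axis=1), axis=1)
    return [SCOREABLE_STAGES[i] for i in pred]
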