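"""Two-phase ("separating") training orchestration and cross-validation.

Phase 1 trains one class-specific CNN per (manipulation set, target stage)
pair on shuffled pooled epoch pairs; phase 2 freezes them, extracts feature
sequences for every record, and trains the BiLSTM sequence classifier.  The
end-to-end baseline couples a single unweighted CNN to the BiLSTM through
its 5-way softmax and optimizes everything jointly on whole-record
sequences.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .cnn import (CNNArchitecture, CNNTrainingConfig, ClassWeights,
                  SleepStageCNN, TrainedCNN, compute_class_weights, train_cnn)
from .io import EpochedRecord
from .manipulation import (SET_ORDER, ManipulationSet, build_pairs_pooled)
from .metrics import (ConfusionMatrix, EvaluationReport, confusion, report,
                      subject_wise_folds)
from .sequence import (BiLSTMConfig, ModelRegistry, SequenceClassifier,
                       TrainedSequenceModel, extract_feature_sequence,
                       predict_sequence, train_bilstm, _masked_ce_and_grad)
from .stages import SCOREABLE_STAGES, StageLabel


@dataclass
class ExperimentConfig:
    """One experiment: which sets, weighted or not, separated or end-to-end."""

    combo: list[ManipulationSet] = field(
        default_factory=lambda: list(SET_ORDER))
    weighted: bool = True
    training_mode: str = "separated"          # "separated" | "end_to_end"
    feature_mode: str = "full"                # "full" | "condensed"
    channel: str = "EEG Fpz-Cz"
    seed: int = 0
    cnn_config: CNNTrainingConfig = field(default_factory=CNNTrainingConfig)
    bilstm_config: BiLSTMConfig = field(default_factory=BiLSTMConfig)
    arch: CNNArchitecture = field(default_factory=CNNArchitecture)

    def __post_init__(self) -> None:
        if self.training_mode not in ("separated", "end_to_end"):
            raise ValueError("training_mode must be separated or end_to_end")
        if self.training_mode == "end_to_end":
            # scenario-A definition: one unweighted CNN on the current epochs
            if self.weighted or [s for s in self.combo] != [ManipulationSet.A_current]:
                raise ValueError(
                    "end_to_end requires weighted=False and combo=[A_current]")


@dataclass
class TrainedEnsemble:
    registry: ModelRegistry
    sequence_model: TrainedSequenceModel
    config: ExperimentConfig
    timings: dict = field(default_factory=dict)

    def cnn_checksum(self) -> str:
        """Stable digest of all CNN parameters (phase-separation witness)."""
        h = hashlib.sha256()
        for key in sorted(self.registry.models, key=lambda k: (k[0].value, k[1].value)):
            for p in self.registry.models[key].model.parameters():
                h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()


def _component_seed(master: int, set_id: ManipulationSet,
                    target: StageLabel | None) -> int:
    """Stable per-(set, class) seed derived from the master seed."""
    tag = f"{master}:{set_id.value}:{'-' if target is None else target.name}"
    digest = hashlib.sha256(tag.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def train_separated(records: list[EpochedRecord],
                    config: ExperimentConfig,
                    verbose: bool = False,
                    checkpoint_dir: "str | None" = None) -> TrainedEnsemble:
    """Phase 1: the CNN ensemble; phase 2: the BiLSTM on frozen features.

    With ``checkpoint_dir`` set, every trained component is saved there and
    components whose checkpoint already exists (same set, class and derived
    seed) are loaded instead of retrained, making interrupted runs
    resumable.
    """
    from pathlib import Path

    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ckpt = None
    if checkpoint_dir is not None:
        ckpt = Path(checkpoint_dir)
        ckpt.mkdir(parents=True, exist_ok=True)
    combo = [s for s in SET_ORDER if s in config.combo]
    registry = ModelRegistry()
    t0 = time.perf_counter()
    for set_id in combo:
        pairs = build_pairs_pooled(records, set_id)
        stage_counts = pairs.stage_counts()
        targets = SCOREABLE_STAGES if config.weighted else (StageLabel.W,)
        for target in targets:
            weights = (compute_class_weights(stage_counts, target)
                       if config.weighted else ClassWeights.uniform())
            seed = _component_seed(config.seed, set_id,
                                   target if config.weighted else None)
            cfg = replace(config.cnn_config, seed=seed)
            path = (None if ckpt is None else
                    ckpt / f"cnn_{set_id.value}_{target.name}_{seed}.npz")
            if path is not None and path.exists():
                from .checkpoints import load_cnn
                trained = load_cnn(path)
            else:
                if verbose:
                    print(f"[phase 1] CNN set={set_id.name} target={target.name}")
                trained = train_cnn(pairs, weights, cfg, arch=config.arch,
                                    set_id=set_id.name, verbose=verbose)
                if path is not None:
                    from .checkpoints import save_cnn
                    save_cnn(path, trained)
            if config.weighted:
                registry.models[(set_id, target)] = trained
            else:
                # the class-agnostic model stands in for all five slots so
                # feature extraction yields one 5-way softmax per set
                for t in SCOREABLE_STAGES:
                    registry.models[(set_id, t)] = trained
    t1 = time.perf_counter()

    sequences = [extract_feature_sequence(registry, rec, combo, mode=_effective_mode(config))
                 for rec in records]
    t2 = time.perf_counter()
    bcfg = replace(config.bilstm_config, seed=config.seed + 9001)
    bpath = None if ckpt is None else ckpt / f"bilstm_{bcfg.seed}.npz"
    if bpath is not None and bpath.exists():
        from .checkpoints import load_sequence_model
        seq_model = load_sequence_model(bpath)
    else:
        if verbose:
            print(f"[phase 2] BiLSTM on d={sequences[0].d} features")
        seq_model = train_bilstm(sequences, bcfg, verbose=verbose)
        seq_model.feature_names = registry.feature_ordering(
            combo, _effective_mode(config))
        if bpath is not None:
            from .checkpoints import save_sequence_model
            save_sequence_model(bpath, seq_model)
    t3 = time.perf_counter()
    return TrainedEnsemble(
        registry=registry, sequence_model=seq_model, config=config,
        timings={"cnn_training_s": t1 - t0, "feature_extraction_s": t2 - t1,
                 "bilstm_training_s": t3 - t2})


def _effective_mode(config: ExperimentConfig) -> str:
    # an unweighted (class-agnostic) registry duplicates one model over the
    # five class slots; condensed mode then recovers its plain 5-way softmax
    return config.feature_mode if config.weighted else "condensed"


def train_end_to_end(records: list[EpochedRecord],
                     config: ExperimentConfig,
                     verbose: bool = False) -> TrainedEnsemble:
    """Jointly optimize a single CNN + BiLSTM on whole-record sequences.

    The CNN feeds the BiLSTM through its 5-way softmax.  Batching is
    sequence-wise (4 records per iteration, as in BiLSTM training) with the
    CNN learning rate; other settings follow the CNN protocol.
    """
    if config.training_mode != "end_to_end":
        raise ValueError("config.training_mode must be end_to_end")
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    seed = _component_seed(config.seed, ManipulationSet.A_current, None)
    cnn = SleepStageCNN(config.arch, seed=seed)
    seq = SequenceClassifier(5, config.bilstm_config.hidden_units, seed=seed + 1)
    softmax_layer = nn.Softmax()
    params = cnn.parameters() + seq.parameters()
    grads = cnn.gradients() + seq.gradients()
    opt = nn.Adam(params, grads, lr=config.cnn_config.learning_rate)
    rng = np.random.default_rng(seed + 2)

    # record-wise 90/10 split mirroring the sequence trainer
    order = rng.permutation(len(records))
    n_train = min(max(int(round(0.9 * len(records))), 1), len(records) - 1)
    train_recs = [records[i] for i in order[:n_train]]
    val_recs = [records[i] for i in order[n_train:]]

    def seq_inputs(recs: list[EpochedRecord]):
        seqs = []
        for r in recs:
            labels = np.array(
                [(lab.value if lab.is_scoreable else StageLabel.W.value)
                 for lab in r.labels], dtype=np.int64)
            seqs.append((r.epochs, labels, r.n_epochs))
        return seqs

    def forward_batch(batch, train_flag):
        lengths = np.array([b[2] for b in batch])
        T = int(lengths.max())
        flat = np.concatenate([b[0] for b in batch], axis=0)
        probs_flat = softmax_layer.forward(cnn.logits(flat, train=train_flag))
        d = probs_flat.shape[1]
        x = np.zeros((len(batch), T, d))
        y = np.zeros((len(batch), T), dtype=np.int64)
        valid = np.zeros((len(batch), T), dtype=bool)
        off = 0
        for n, (eps, labels, ln) in enumerate(batch):
            x[n, :ln] = probs_flat[off:off + ln]
            y[n, :ln] = labels
            valid[n, :ln] = True
            off += ln
        logits = seq.logits(x, lengths, train=train_flag)
        return logits, y, valid, lengths

    def backward_batch(dlogits, batch, valid):
        dx = seq.backward(dlogits)  # (N, T, 5)
        pieces = []
        for n, (eps, labels, ln) in enumerate(batch):
            pieces.append(dx[n, :ln])
        dprobs_flat = np.concatenate(pieces, axis=0)
        dlogits_cnn = softmax_layer.backward(dprobs_flat)
        cnn.backward(dlogits_cnn)

    def validate() -> float:
        total, n = 0.0, 0
        for rec in val_recs:
            batch = seq_inputs([rec])
            logits, y, valid, _ = forward_batch(batch, False)
            loss, _ = _masked_ce_and_grad(logits, y, valid)
            total += loss * rec.n_epochs
            n += rec.n_epochs
        return total / n

    train_seqs = seq_inputs(train_recs)
    bcfg = config.bilstm_config
    best_loss = np.inf
    best_state = cnn.get_state() + seq.get_state()
    bad, it, stop = 0, 0, False
    history: list[dict] = []
    for _pass in range(config.cnn_config.max_training_epochs):
        perm = rng.permutation(len(train_seqs))
        for lo in range(0, len(perm), bcfg.batch_size):
            batch = [train_seqs[i] for i in perm[lo:lo + bcfg.batch_size]]
            logits, y, valid, _ = forward_batch(batch, True)
            loss, dlogits = _masked_ce_and_grad(logits, y, valid)
            if not np.isfinite(loss):
                raise FloatingPointError(f"NaN loss at iteration {it}")
            backward_batch(dlogits, batch, valid)
            opt.step()
            it += 1
            if it % bcfg.validation_interval == 0:
                vloss = validate()
                history.append({"iteration": it, "train_loss": loss,
                                "val_loss": vloss})
                if verbose:
                    print(f"  it {it}: train {loss:.4f} val {vloss:.4f}")
                if vloss < best_loss:
                    best_loss = vloss
                    best_state = cnn.get_state() + seq.get_state()
                    bad = 0
                else:
                    bad += 1
                    if bad >= bcfg.patience:
                        stop = True
                        break
        if stop:
            break
    n_cnn_state = len(cnn.get_state())
    cnn.set_state(best_state[:n_cnn_state])
    seq.set_state(best_state[n_cnn_state:])

    trained_cnn = TrainedCNN(model=cnn, weights=ClassWeights.uniform(),
                             history=history, set_id="A", target_class="-",
                             seed=seed)
    registry = ModelRegistry()
    for t in SCOREABLE_STAGES:
        registry.models[(ManipulationSet.A_current, t)] = trained_cnn
    seq_trained = TrainedSequenceModel(model=seq, history=history, seed=seed)
    seq_trained.feature_names = registry.feature_ordering(
        [ManipulationSet.A_current], "condensed")
    return TrainedEnsemble(registry=registry, sequence_model=seq_trained,
                           config=config)


def predict_record(ensemble: TrainedEnsemble,
                   rec: EpochedRecord) -> tuple[list[StageLabel], np.ndarray]:
    """Predict one stage per epoch (all positions, including masked ones).

    Returns (labels, eval_mask); the mask marks epochs valid for scoring.
    """
    if rec.epochs.shape[1] != ensemble.config.arch.input_length:
        raise ValueError(
            f"record epochs have {rec.epochs.shape[1]} samples; the ensemble "
            f"was trained on {ensemble.config.arch.input_length} "
            "(check channel/sampling-rate provenance)")
    combo = [s for s in SET_ORDER if s in ensemble.config.combo]
    feats = extract_feature_sequence(
        ensemble.registry, rec, combo, mode=_effective_mode(ensemble.config))
    return predict_sequence(ensemble.sequence_model, feats), feats.eval_mask


def time_inference(ensemble: TrainedEnsemble,
                   rec: EpochedRecord) -> dict[str, float]:
    """Per-record feed-forward timings (seconds) for the CNN ensemble and
    the BiLSTM, plus the total."""
    combo = [s for s in SET_ORDER if s in ensemble.config.combo]
    t0 = time.perf_counter()
    feats = extract_feature_sequence(
        ensemble.registry, rec, combo, mode=_effective_mode(ensemble.config))
    t1 = time.perf_counter()
    predict_sequence(ensemble.sequence_model, feats)
    t2 = time.perf_counter()
    return {"cnn_s": t1 - t0, "bilstm_s": t2 - t1, "total_s": t2 - t0}


def evaluate_records(ensemble: TrainedEnsemble,
                     records: list[EpochedRecord]) -> EvaluationReport:
    """Pooled evaluation of an ensemble over records."""
    cm = ConfusionMatrix()
    for rec in records:
        pred, mask = predict_record(ensemble, rec)
        cm = cm + confusion(rec.labels, pred, mask)
    return report(cm)


def cross_validate(records: list[EpochedRecord], config: ExperimentConfig,
                   k: int, verbose: bool = False
                   ) -> tuple[EvaluationReport, list[EvaluationReport]]:
    """Subject-wise k-fold CV; pooled confusion across folds plus per-fold
    reports.  With k equal to the subject count this is leave-one-subject-out.
    """
    assignment = subject_wise_folds([r.subject_id for r in records], k,
                                    seed=config.seed)
    pooled = ConfusionMatrix()
    fold_reports: list[EvaluationReport] = []
    train_fn = (train_separated if config.training_mode == "separated"
                else train_end_to_end)
    for fold in range(k):
        train_recs = [r for r in records if assignment[r.subject_id] != fold]
        test_recs = [r for r in records if assignment[r.subject_id] == fold]
        if verbose:
            print(f"[fold {fold + 1}/{k}] train {len(train_recs)} records, "
                  f"test {len(test_recs)}")
        ensemble = train_fn(train_recs, config, verbose=verbose)
        cm = ConfusionMatrix()
        for rec in test_recs:
            pred, mask = predict_record(ensemble, rec)
            cm = cm + confusion(rec.labels, pred, mask)
        pooled = pooled + cm
        fold_reports.append(report(cm))
    return report(pooled), fold_reports


def run_combination_experiment(records: list[EpochedRecord],
                               combos: list[list[ManipulationSet]],
                               base_config: ExperimentConfig, k: int,
                               verbose: bool = False
                               ) -> dict[str, EvaluationReport]:
    """Train and evaluate each set combination under identical folds/seeds."""
    if not combos:
        raise ValueError("no combinations given")
    out: dict[str, EvaluationReport] = {}
    for combo in combos:
        name = "+".join(s.value for s in SET_ORDER if s in combo)
        cfg = replace(base_config, combo=[s for s in SET_ORDER if s in combo])
        pooled, _ = cross_validate(records, cfg, k, verbose=verbose)
        out[name] = pooled
    return out
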