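"""Flat-file checkpoint store for trained components.

Each CNN and the sequence model serialize to a ``.npz`` holding the full
parameter state (including batch-norm running statistics), the architecture
descriptor and the training history.  `train_separated` uses these to skip
components that already exist for identical (config, seed), which makes
interrupted runs resumable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cnn import (CNNArchitecture, ClassWeights, SleepStageCNN, TrainedCNN)
from .sequence import SequenceClassifier, TrainedSequenceModel
from .stages import StageLabel


def save_cnn(path: str | Path, trained: TrainedCNN) -> None:
    meta = {
        "arch": vars(trained.model.arch),
        "weights_w": trained.weights.w.tolist(),
        "weights_p": trained.weights.p.tolist(),
        "target_class": trained.weights.target_class.name,
        "class_count": trained.weights.class_count,
        "total": trained.weights.total,
        "set_id": trained.set_id,
        "seed": trained.seed,
        "history": trained.history,
    }
    state = trained.model.get_state()
    np.savez(path, meta=json.dumps(meta),
             **{f"state_{i}": s for i, s in enumerate(state)})


def load_cnn(path: str | Path) -> TrainedCNN:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        state = [data[f"state_{i}"]
                 for i in range(sum(1 for k in data.files if k.startswith("state_")))]
    model = SleepStageCNN(CNNArchitecture(**meta["arch"]), seed=meta["seed"])
    model.set_state(state)
    weights = ClassWeights(
        target_class=StageLabel[meta["target_class"]],
        w=np.array(meta["weights_w"]), p=np.array(meta["weights_p"]),
        class_count=meta["class_count"], total=meta["total"])
    return TrainedCNN(model=model, weights=weights, history=meta["history"],
                      set_id=meta["set_id"],
                      target_class=meta["target_class"], seed=meta["seed"])


def save_sequence_model(path: str | Path,
                        trained: TrainedSequenceModel) -> None:
    model = trained.model
    meta = {
        "input_dim": model.input_dim,
        "hidden_units": model.bilstm.H,
        "seed": trained.seed,
        "history": trained.history,
        "feature_names": trained.feature_names,
    }
    np.savez(path, meta=json.dumps(meta),
             **{f"state_{i}": s for i, s in enumerate(model.get_state())})


def load_sequence_model(path: str | Path) -> TrainedSequenceModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        state = [data[f"state_{i}"]
                 for i in range(sum(1 for k in data.files if k.startswith("state_")))]
    model = SequenceClassifier(meta["input_dim"], meta["hidden_units"],
                               seed=meta["seed"])
    model.set_state(state)
    out = TrainedSequenceModel(model=model, history=meta["history"],
                               seed=meta["seed"])
    out.feature_names = meta["feature_names"]
    return out
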