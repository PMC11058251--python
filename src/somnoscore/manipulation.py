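"""Epoch-shifted training views and the epoch-wise train/validation split.

The three "data manipulation" sets pair an epoch's signal with the *current*
epoch's stage: set A uses the current epoch's own signal, set B the previous
epoch's (right shift, first epoch duplicated), set C the next epoch's (left
shift, last epoch duplicated).  Shifting never crosses record boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import EpochedRecord
from .stages import StageLabel


class ManipulationSet(Enum):
    A_current = "A"
    B_previous = "B"
    C_next = "C"


#: Canonical set ordering for feature concatenation: previous, current, next.
SET_ORDER: tuple[ManipulationSet, ...] = (
    ManipulationSet.B_previous, ManipulationSet.A_current, ManipulationSet.C_next)


@dataclass
class EpochPairDataset:
    """Rows of (signal, current-epoch target) with provenance."""

    signals: np.ndarray              # (n, samples_per_epoch)
    targets: list[StageLabel]        # current-epoch labels, scoreable only
    provenance: list[tuple[str, int]]  # (record_id, epoch_index) per row

    def __post_init__(self) -> None:
        n = self.signals.shape[0]
        if len(self.targets) != n or len(self.provenance) != n:
            raise ValueError("row counts must agree")

    def __len__(self) -> int:
        return self.signals.shape[0]

    def target_indices(self) -> np.ndarray:
        return np.array([t.value for t in self.targets], dtype=np.int64)

    def stage_counts(self) -> dict[StageLabel, int]:
        counts: dict[StageLabel, int] = {}
        for t in self.targets:
            counts[t] = counts.get(t, 0) + 1
        return counts

    @staticmethod
    def concatenate(parts: list["EpochPairDataset"]) -> "EpochPairDataset":
        return EpochPairDataset(
            signals=np.concatenate([p.signals for p in parts], axis=0),
            targets=[t for p in parts for t in p.targets],
            provenance=[pv for p in parts for pv in p.provenance],
        )


def shift_sequence(epochs: np.ndarray, set_id: ManipulationSet) -> np.ndarray:
    """Shift a record's epoch matrix according to the manipulation set.

    A: identity.  B: right shift with the first epoch duplicated.  C: left
    shift with the last epoch duplicated.  Output length equals input length.
    """
    epochs = np.asarray(epochs)
    if epochs.shape[0] < 1:
        raise ValueError("need at least one epoch")
    if set_id is ManipulationSet.A_current:
        return epochs.copy()
    if set_id is ManipulationSet.B_previous:
        return np.concatenate([epochs[:1], epochs[:-1]], axis=0)
    return np.concatenate([epochs[1:], epochs[-1:]], axis=0)


def build_pairs(rec: EpochedRecord, set_id: ManipulationSet,
                drop_artifact_signals: bool = False) -> EpochPairDataset:
    """Build (shifted signal, current label) pairs for one record.

    Rows whose *target* is MOVEMENT/UNKNOWN are dropped.  Rows whose shifted
    *signal* originated in an excluded epoch are kept by default (only the
    scored target governs exclusion); set ``drop_artifact_signals`` to drop
    those too.
    """
    shifted = shift_sequence(rec.epochs, set_id)
    n = rec.n_epochs
    if set_id is ManipulationSet.A_current:
        src = np.arange(n)
    elif set_id is ManipulationSet.B_previous:
        src = np.maximum(np.arange(n) - 1, 0)
    else:
        src = np.minimum(np.arange(n) + 1, n - 1)

    keep = rec.included.copy()
    if drop_artifact_signals:
        keep &= rec.included[src]
    idx = np.nonzero(keep)[0]
    return EpochPairDataset(
        signals=shifted[idx],
        targets=[rec.labels[i] for i in idx],
        provenance=[(rec.record_id, int(i)) for i in idx],
    )


def build_pairs_pooled(records: list[EpochedRecord], set_id: ManipulationSet,
                       drop_artifact_signals: bool = False) -> EpochPairDataset:
    """Pool pairs over records; shifting is done per record first."""
    return EpochPairDataset.concatenate(
        [build_pairs(r, set_id, drop_artifact_signals) for r in records])


def shuffle_split(pairs: EpochPairDataset, train_fraction: float = 0.7,
                  seed: int = 0) -> tuple[EpochPairDataset, EpochPairDataset]:
    """Epoch-wise shuffled split into train/validation parts.

    The split is over pooled epochs (not subjects): disjoint, exhaustive,
    deterministic given the seed, with ``round(train_fraction * n)`` training
    rows.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)

    def take(idx: np.ndarray) -> EpochPairDataset:
        return EpochPairDataset(
            signals=pairs.signals[idx],
            targets=[pairs.targets[i] for i in idx],
            provenance=[pairs.provenance[i] for i in idx],
        )

    return take(perm[:n_train]), take(perm[n_train:])
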