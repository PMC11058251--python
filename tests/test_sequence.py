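"""Feature-sequence assembly and the BiLSTM sequence classifier."""

import numpy as np
import pytest

from somnoscore.io import EpochedRecord
from somnoscore.manipulation import SET_ORDER, ManipulationSet
from somnoscore.sequence import (BiLSTMConfig, FeatureSequence, ModelRegistry,
                                 SequenceClassifier, _masked_ce_and_grad,
                                 _pad_batch, extract_feature_sequence,
                                 predict_sequence, train_bilstm)
from somnoscore.stages import SCOREABLE_STAGES, StageLabel


class _StubCNN:
    """Deterministic stand-in feature extractor (synthetic softmax outputs)."""

    def __init__(self, peak):
        self.peak = peak

    def predict_proba(self, x):
        out = np.full((x.shape[0], 5), 0.1)
        out[:, self.peak] = 0.6
        return out


def _stub_registry(sets=SET_ORDER):
    reg = ModelRegistry()
    for s in sets:
        for i, target in enumerate(SCOREABLE_STAGES):
            reg.models[(s, target)] = _StubCNN(i)
    return reg


def _epoched(labels, rng):
    n = len(labels)
    return EpochedRecord(rng.normal(size=(n, 3000)), list(labels),
                         np.array([l.is_scoreable for l in labels]),
                         "S0", "S0R0")


class TestExtractFeatureSequence:
    def test_developed_configuration_is_75_wide(self, rng):
        rec = _epoched([StageLabel.N2] * 10, rng)
        feats = extract_feature_sequence(_stub_registry(), rec)
        assert feats.features.shape == (10, 75)

    def test_single_set_modes(self, rng):
        rec = _epoched([StageLabel.N2] * 10, rng)
        reg = _stub_registry([ManipulationSet.A_current])
        full = extract_feature_sequence(reg, rec, [ManipulationSet.A_current])
        cond = extract_feature_sequence(reg, rec, [ManipulationSet.A_current],
                                        mode="condensed")
        assert full.features.shape == (10, 25)
        assert cond.features.shape == (10, 5)

    def test_blocks_sum_to_one_in_full_mode(self, rng):
        rec = _epoched([StageLabel.W] * 6, rng)
        feats = extract_feature_sequence(_stub_registry(), rec).features
        assert feats.min() >= 0 and feats.max() <= 1
        for block in range(15):
            np.testing.assert_allclose(
                feats[:, block * 5:(block + 1) * 5].sum(axis=1), 1.0, atol=1e-6)

    def test_artifacts_relabeled_w_and_masked(self, rng):
        rec = _epoched([StageLabel.N2, StageLabel.MOVEMENT, StageLabel.UNKNOWN],
                       rng)
        feats = extract_feature_sequence(_stub_registry(), rec)
        assert feats.labels.tolist() == [StageLabel.N2.value,
                                         StageLabel.W.value,
                                         StageLabel.W.value]
        assert feats.eval_mask.tolist() == [True, False, False]

    def test_missing_registry_entry_raises(self, rng):
        reg = _stub_registry([ManipulationSet.A_current])
        rec = _epoched([StageLabel.W] * 3, rng)
        with pytest.raises(KeyError):
            extract_feature_sequence(reg, rec, [ManipulationSet.B_previous])


def _onehot_sequences(rng, n_records=8, length=30, d=5):
    """Feature vector is the one-hot of the true stage: trivially learnable."""
    seqs = []
    for r in range(n_records):
        y = rng.integers(0, 5, length)
        x = np.eye(5)[y] * 2.0 - 1.0
        seqs.append(FeatureSequence(
            features=x, labels=y, eval_mask=np.ones(length, bool),
            record_id=f"r{r}"))
    return seqs


class TestTrainBilstm:
    def test_learns_onehot_toy(self, rng):
        seqs = _onehot_sequences(rng)
        cfg = BiLSTMConfig(hidden_units=16, max_training_epochs=60,
                           validation_interval=5, patience=8, seed=0)
        trained = train_bilstm(seqs, cfg)
        test = _onehot_sequences(np.random.default_rng(99), n_records=2)
        correct = total = 0
        for s in test:
            pred = predict_sequence(trained, s)
            correct += sum(p.value == t for p, t in zip(pred, s.labels))
            total += s.n_epochs
        assert correct / total >= 0.99

    def test_padding_masked_out_of_loss(self, rng):
        """Batched variable-length loss equals the valid-count-weighted mean
        of per-sequence losses."""
        seqs = [_onehot_sequences(rng, 1, 10)[0],
                _onehot_sequences(rng, 1, 7)[0]]
        model = SequenceClassifier(5, hidden_units=8, seed=1)
        x, y, valid, lengths = _pad_batch(seqs)
        joint, _ = _masked_ce_and_grad(model.logits(x, lengths), y, valid)
        parts = []
        for s in seqs:
            xs, ys, vs, ls = _pad_batch([s])
            loss, _ = _masked_ce_and_grad(model.logits(xs, ls), ys, vs)
            parts.append((loss, s.n_epochs))
        expected = sum(l * n for l, n in parts) / sum(n for _, n in parts)
        assert joint == pytest.approx(expected, abs=1e-6)

    def test_patience_stops_at_second_validation_when_frozen(self, rng):
        # zero learning rate makes the validation loss exactly constant
        # (no batch-norm in this model), so patience-1 stops at validation 2
        seqs = _onehot_sequences(rng, n_records=6, length=10)
        cfg = BiLSTMConfig(hidden_units=8, max_training_epochs=100,
                           validation_interval=1, patience=1,
                           learning_rate=0.0, seed=0)
        trained = train_bilstm(seqs, cfg)
        assert len(trained.history) == 2

    def test_deterministic_given_seed(self, rng):
        seqs = _onehot_sequences(rng, n_records=4, length=12)
        cfg = BiLSTMConfig(hidden_units=8, max_training_epochs=3,
                           validation_interval=2, seed=5)
        a = train_bilstm(seqs, cfg)
        b = train_bilstm(seqs, cfg)
        for pa, pb in zip(a.model.parameters(), b.model.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_inconsistent_dimensions_rejected(self, rng):
        seqs = _onehot_sequences(rng, n_records=2)
        seqs[1].features = np.zeros((seqs[1].n_epochs, 7))
        with pytest.raises(ValueError):
            train_bilstm(seqs, BiLSTMConfig(hidden_units=8))


class TestPredictSequence:
    def test_output_length_matches_input(self, rng):
        model = SequenceClassifier(5, hidden_units=8, seed=0)
        s = _onehot_sequences(rng, 1, 23)[0]
        assert len(predict_sequence(model, s)) == 23

    def test_tie_breaks_toward_lower_stage_index(self):
        # a zero-weight head yields exactly tied posteriors everywhere
        model = SequenceClassifier(5, hidden_units=8, seed=0)
        model.head.W[...] = 0.0
        model.head.b[...] = 0.0
        s = FeatureSequence(features=np.zeros((4, 5)),
                            labels=np.zeros(4, dtype=np.int64),
                            eval_mask=np.ones(4, bool), record_id="t")
        assert all(p is StageLabel.W for p in predict_sequence(model, s))

    def test_dimension_mismatch_rejected(self, rng):
        model = SequenceClassifier(5, hidden_units=8, seed=0)
        s = FeatureSequence(features=np.zeros((4, 9)),
                            labels=np.zeros(4, dtype=np.int64),
                            eval_mask=np.ones(4, bool), record_id="t")
        with pytest.raises(ValueError):
            predict_sequence(model, s)
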