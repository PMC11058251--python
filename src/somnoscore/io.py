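"""Polysomnography record I/O, epoching and in-bed trimming.

Signals are kept in microvolts.  Reading EDF/EDF+ goes through :mod:`mne`;
a deliberately minimal EDF *writer* is included so synthetic cohorts can be
serialized to standard files without extra dependencies.  Hypnograms come from
a two-column CSV dialect (``onset_epoch,label``) or from an EDF+ annotation
track; both pass through :func:`somnoscore.stages.map_rk_to_aasm`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .stages import StageLabel, map_rk_to_aasm

EPOCH_SECONDS = 30.0


class MissingChannelError(KeyError):
    """Requested channel not present in the EDF file."""


class EdfFormatError(IOError):
    """File is not a readable EDF/EDF+."""


@dataclass
class SleepRecord:
    """A single-channel EEG recording in microvolts."""

    subject_id: str
    record_id: str
    channel_name: str
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")

    @property
    def duration_seconds(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class Hypnogram:
    """One stage label per 30-s epoch."""

    labels: list[StageLabel]
    epoch_duration: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        if self.epoch_duration != EPOCH_SECONDS:
            raise ValueError("epoch_duration is fixed at 30 s")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class EpochedRecord:
    """30-s epochs of one record with labels and an inclusion mask.

    ``included[e]`` is False exactly where ``labels[e]`` is MOVEMENT or
    UNKNOWN; those epochs are never CNN training targets and are excluded
    from evaluation, but keep their position in the sequence.
    """

    epochs: np.ndarray  # (n_epochs, samples_per_epoch), µV
    labels: list[StageLabel]
    included: np.ndarray  # (n_epochs,) bool
    subject_id: str
    record_id: str
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.included = np.asarray(self.included, dtype=bool)
        n = self.epochs.shape[0]
        if len(self.labels) != n or self.included.shape[0] != n:
            raise ValueError("labels/mask lengths must equal the epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


# ---------------------------------------------------------------------------
# EDF reading (via mne) and a minimal writer for fixtures
# ---------------------------------------------------------------------------

def read_record(edf_path: str | Path, channel: str,
                subject_id: str = "", record_id: str = "") -> SleepRecord:
    """Read one channel of an EDF/EDF+ file as a :class:`SleepRecord`.

    The samples are returned exactly as stored (converted to µV); no
    filtering or rescaling is applied and the stored sampling rate is kept.
    """
    import mne

    path = Path(edf_path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    except Exception as exc:  # mne raises assorted errors on bad headers
        raise EdfFormatError(f"unreadable EDF file {path}: {exc}") from exc
    if channel not in raw.ch_names:
        raise MissingChannelError(
            f"channel {channel!r} not in {path.name}; available: {raw.ch_names}")
    raw = raw.pick([channel])
    data = raw.get_data()[0] * 1e6  # mne returns volts for EEG channels
    return SleepRecord(
        subject_id=subject_id or path.stem,
        record_id=record_id or path.stem,
        channel_name=channel,
        samples=data,
        sampling_rate=float(raw.info["sfreq"]),
    )


def _edf_field(value: str, width: int) -> bytes:
    out = value.encode("ascii")[:width]
    return out + b" " * (width - len(out))


def write_edf(path: str | Path, record: SleepRecord) -> None:
    """Write a single-channel EDF file (int16, µV physical units).

    Minimal but standard-conformant: 256-byte fixed header, one signal header,
    data records of one second (or one single record when the length is not a
    whole number of seconds).  Intended for fixture generation; round-trips
    through any EDF reader to within one quantization step.
    """
    path = Path(path)
    x = np.asarray(record.samples, dtype=np.float64)
    rate = record.sampling_rate
    if x.size % int(rate) == 0 and rate == int(rate):
        spr = int(rate)  # samples per data record (1-s records)
        n_records = x.size // spr
        record_duration = 1.0
    else:
        spr = x.size
        n_records = 1
        record_duration = x.size / rate

    phys_max = max(float(np.max(np.abs(x))), 1.0) * 1.0001
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((x - phys_min) * scale + dig_min).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(record.subject_id, 80),
        _edf_field(record.record_id, 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * 2), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field(f"{record_duration:g}", 8),
        _edf_field("1", 4),
    ])
    sig_header = b"".join([
        _edf_field(record.channel_name, 16),
        _edf_field("", 80),
        _edf_field("uV", 8),
        _edf_field(f"{phys_min:.6g}", 8),
        _edf_field(f"{phys_max:.6g}", 8),
        _edf_field(str(dig_min), 8),
        _edf_field(str(dig_max), 8),
        _edf_field("", 80),
        _edf_field(str(spr), 8),
        _edf_field("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital.tobytes())


# ---------------------------------------------------------------------------
# Hypnogram I/O
# ---------------------------------------------------------------------------

def read_hypnogram_csv(path: str | Path) -> Hypnogram:
    """Read the two-column CSV dialect ``onset_epoch,label``.

    Epoch indices must be 0-based and contiguous from 0; labels are R&K /
    Sleep-EDF tokens mapped through :func:`map_rk_to_aasm`.
    """
    df = pd.read_csv(path, dtype={"label": str})
    if not {"onset_epoch", "label"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns onset_epoch,label")
    df = df.sort_values("onset_epoch")
    if not np.array_equal(df["onset_epoch"].to_numpy(), np.arange(len(df))):
        raise ValueError(f"{path}: onset_epoch must be contiguous from 0")
    return Hypnogram([map_rk_to_aasm(t) for t in df["label"]])


def write_hypnogram_csv(path: str | Path, hypnogram: Hypnogram) -> None:
    tokens = {StageLabel.W: "W", StageLabel.N1: "1", StageLabel.N2: "2",
              StageLabel.N3: "3", StageLabel.REM: "R",
              StageLabel.MOVEMENT: "M", StageLabel.UNKNOWN: "?"}
    df = pd.DataFrame({
        "onset_epoch": np.arange(len(hypnogram)),
        "label": [tokens[s] for s in hypnogram.labels],
    })
    df.to_csv(path, index=False)


def read_hypnogram_edf_annotations(path: str | Path) -> Hypnogram:
    """Read a hypnogram from an EDF+ annotation track (Sleep-EDF style).

    Annotation descriptions such as "Sleep stage W" are expanded to one label
    per 30-s epoch according to their durations.
    """
    import mne

    ann = mne.read_annotations(str(path))
    labels: list[StageLabel] = []
    for desc, dur in zip(ann.description, ann.duration):
        stage = map_rk_to_aasm(desc)
        labels.extend([stage] * int(round(dur / EPOCH_SECONDS)))
    return Hypnogram(labels)


# ---------------------------------------------------------------------------
# Resampling, epoching, trimming
# ---------------------------------------------------------------------------

def resample_to(record: SleepRecord, target_rate: float) -> SleepRecord:
    """Polyphase-resample a record to ``target_rate`` Hz.

    Identity (bit-exact) when the rates already match.  Duration is preserved
    to within one sample.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == record.sampling_rate:
        return record
    from fractions import Fraction

    frac = Fraction(target_rate / record.sampling_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    y = resample_poly(record.samples, up, down)
    return replace(record, samples=y, sampling_rate=float(target_rate))


def epoch_record(record: SleepRecord, hypnogram: Hypnogram) -> EpochedRecord:
    """Segment a record into 30-s epochs aligned with its hypnogram.

    The epoch count is the smaller of what the signal and the hypnogram
    support; trailing samples that do not fill a whole epoch are dropped.
    The inclusion mask is False for MOVEMENT/UNKNOWN epochs.
    """
    spe = int(round(EPOCH_SECONDS * record.sampling_rate))
    n_signal = record.samples.size // spe
    if n_signal == 0:
        raise ValueError("record shorter than one 30-s epoch")
    n = min(n_signal, len(hypnogram))
    if n == 0:
        raise ValueError("zero usable epochs")
    epochs = record.samples[: n * spe].reshape(n, spe)
    labels = list(hypnogram.labels[:n])
    included = np.array([lab.is_scoreable for lab in labels], dtype=bool)
    return EpochedRecord(
        epochs=epochs, labels=labels, included=included,
        subject_id=record.subject_id, record_id=record.record_id,
        sampling_rate=record.sampling_rate,
    )


def trim_to_in_bed(rec: EpochedRecord, margin_epochs: int = 60) -> EpochedRecord:
    """Trim to the in-bed period: first-to-last sleep epoch ± margin.

    The margin default of 60 epochs is the conventional 30 minutes.  Records
    with no sleep-scored epoch are returned unchanged with a warning.
    """
    sleep_idx = [i for i, lab in enumerate(rec.labels) if lab.is_sleep]
    if not sleep_idx:
        warnings.warn(
            f"record {rec.record_id}: no sleep-scored epochs; not trimmed",
            stacklevel=2)
        return rec
    first_sleep, last_sleep = sleep_idx[0], sleep_idx[-1]
    lo = max(0, first_sleep - margin_epochs)
    hi = min(rec.n_epochs - 1, last_sleep + margin_epochs)
    return EpochedRecord(
        epochs=rec.epochs[lo:hi + 1],
        labels=rec.labels[lo:hi + 1],
        included=rec.included[lo:hi + 1],
        subject_id=rec.subject_id, record_id=rec.record_id,
        sampling_rate=rec.sampling_rate,
    )


def load_epoched_record(edf_path: str | Path, hypnogram_path: str | Path,
                        channel: str, target_rate: float = 100.0,
                        margin_epochs: int = 60,
                        subject_id: str = "", record_id: str = "") -> EpochedRecord:
    """Convenience loader: read, resample if needed, epoch and trim."""
    rec = read_record(edf_path, channel, subject_id=subject_id, record_id=record_id)
    if rec.sampling_rate != target_rate:
        rec = resample_to(rec, target_rate)
    hyp_path = Path(hypnogram_path)
    if hyp_path.suffix.lower() == ".csv":
        hyp = read_hypnogram_csv(hyp_path)
    else:
        hyp = read_hypnogram_edf_annotations(hyp_path)
    return trim_to_in_bed(epoch_record(rec, hyp), margin_epochs=margin_epochs)
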