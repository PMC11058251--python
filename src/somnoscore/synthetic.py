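"""Seeded synthetic polysomnography cohorts.

Two layers of structure are emulated.  Hypnograms come from a first-order
Markov chain over {W, N1, N2, N3, REM} whose defaults are strongly diagonal
(stage continuity) and N2-favouring, reproducing the characteristic stage
imbalance of overnight recordings (N2 dominant, N1 rare).  EEG epochs are
stage-conditioned mixtures of band-limited oscillations (delta/theta/alpha/
sigma/beta) over a 1/f background, with amplitude scales that fall in the
physiological range: high-amplitude slow activity in N3, alpha-dominant
low-voltage wake, sigma spindle bursts in N2.

The generator is fully deterministic under (config, seed): every record draws
from its own stream keyed by (seed, subject, record), so cohorts survive
parallel or partial regeneration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Hypnogram, SleepRecord, write_edf, write_hypnogram_csv
from .stages import SCOREABLE_STAGES, StageLabel

#: Frequency bands (Hz) used for the stage-conditioned spectra.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (11.0, 16.0),
    "beta": (16.0, 30.0),
}
_BAND_NAMES = tuple(BANDS)


@dataclass
class StageSpectralProfile:
    """Per-stage band weights, amplitude scales and 1/f background.

    ``band_weights[stage]`` are relative (nonnegative) powers over the five
    bands in the order delta, theta, alpha, sigma, beta; ``amplitudes`` are
    RMS scales in µV.  Defaults follow the textbook stage signatures.
    """

    band_weights: dict[StageLabel, np.ndarray] = field(default_factory=lambda: {
        #                 delta theta alpha sigma beta
        StageLabel.W:   np.array([0.10, 0.15, 0.55, 0.05, 0.15]),
        StageLabel.N1:  np.array([0.20, 0.55, 0.10, 0.05, 0.10]),
        StageLabel.N2:  np.array([0.30, 0.25, 0.05, 0.35, 0.05]),
        StageLabel.N3:  np.array([0.80, 0.12, 0.03, 0.03, 0.02]),
        StageLabel.REM: np.array([0.15, 0.45, 0.08, 0.02, 0.30]),
    })
    amplitudes: dict[StageLabel, float] = field(default_factory=lambda: {
        StageLabel.W: 30.0, StageLabel.N1: 40.0, StageLabel.N2: 60.0,
        StageLabel.N3: 110.0, StageLabel.REM: 45.0,
    })
    background_exponent: float = 1.0
    background_fraction: float = 0.25  # share of total power given to 1/f noise
    n2_spindles_per_epoch: tuple[int, int] = (2, 5)  # uniform range, inclusive

    def __post_init__(self) -> None:
        for stage, w in self.band_weights.items():
            w = np.asarray(w, dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError(f"profile for {stage}: need a positive band weight")
            self.band_weights[stage] = w


@dataclass
class HypnogramModel:
    """First-order Markov model over the five scoreable stages.

    ``artifact_rate`` is the probability that an epoch is independently
    relabeled MOVEMENT or UNKNOWN (each half as likely).
    """

    transition_matrix: np.ndarray = field(default_factory=lambda: _default_transitions())
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0, 0.0]))
    artifact_rate: float = 0.02

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (5, 5) or (P < 0).any():
            raise ValueError("transition matrix must be 5x5 nonnegative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        self.transition_matrix = P
        pi0 = np.asarray(self.initial_distribution, dtype=float)
        if pi0.shape != (5,) or (pi0 < 0).any() or not np.isclose(pi0.sum(), 1.0):
            raise ValueError("initial distribution must be a 5-probability vector")
        self.initial_distribution = pi0
        if not 0 <= self.artifact_rate < 0.1:
            raise ValueError("artifact_rate must be in [0, 0.1)")

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution by eigen-analysis of the transition matrix."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()


def _default_transitions() -> np.ndarray:
    """Diagonal-dominant, N2-favouring defaults.

    Stationary prevalences approximately W .18, N1 .06, N2 .44, N3 .14,
    REM .18 — the overnight imbalance (N2 dominant, N1 rare) that the
    class-weighted loss is designed for.
    """
    #        W      N1     N2     N3     REM
    P = np.array([
        [0.880, 0.050, 0.045, 0.005, 0.020],   # W
        [0.120, 0.560, 0.270, 0.005, 0.045],   # N1
        [0.025, 0.010, 0.880, 0.040, 0.045],   # N2
        [0.015, 0.005, 0.095, 0.880, 0.005],   # N3
        [0.025, 0.015, 0.075, 0.005, 0.880],   # REM
    ])
    return P / P.sum(axis=1, keepdims=True)


@dataclass
class SyntheticCohortConfig:
    """Cohort-level knobs: sizes, rate, seed, inter-subject gain jitter."""

    n_subjects: int = 20
    records_per_subject: int = 1
    epochs_per_record: int = 200
    sampling_rate: float = 100.0
    seed: int = 0
    profile: StageSpectralProfile = field(default_factory=StageSpectralProfile)
    model: HypnogramModel = field(default_factory=HypnogramModel)
    gain_jitter: float = 0.15  # fractional std of per-subject amplitude gain

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.records_per_subject, self.epochs_per_record) <= 0:
            raise ValueError("cohort counts must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _record_rng(seed: int, subject: int, record: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, subject, record]))


def generate_hypnogram(model: HypnogramModel, n_epochs: int,
                       seed: int | np.random.Generator = 0) -> list[StageLabel]:
    """Sample a hypnogram from the Markov model; artifacts injected i.i.d."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.empty(n_epochs, dtype=int)
    states[0] = rng.choice(5, p=model.initial_distribution)
    P = model.transition_matrix
    # cumulative rows + uniform draws: one rng call, fast and deterministic
    cum = np.cumsum(P, axis=1)
    u = rng.random(n_epochs)
    for t in range(1, n_epochs):
        states[t] = min(int(np.searchsorted(cum[states[t - 1]], u[t], side="right")), 4)
    labels = [SCOREABLE_STAGES[s] for s in states]
    if model.artifact_rate > 0:
        hit = rng.random(n_epochs) < model.artifact_rate
        kind = rng.random(n_epochs) < 0.5
        for i in np.nonzero(hit)[0]:
            labels[i] = StageLabel.MOVEMENT if kind[i] else StageLabel.UNKNOWN
    return labels


def _band_noise(rng: np.random.Generator, n: int, rate: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise via Fourier-domain masking."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec = np.zeros(freqs.size, dtype=complex)
    band = (freqs >= lo) & (freqs <= hi)
    k = int(band.sum())
    spec[band] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def synthesize_epoch(profile: StageSpectralProfile, stage: StageLabel,
                     rate: float = 100.0,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Synthesize one 30-s EEG epoch for a stage (µV).

    MOVEMENT/UNKNOWN epochs reuse the wake profile with added broadband
    noise.  Deterministic given (profile, stage, rate, seed).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(30.0 * rate))
    base_stage = stage if stage.is_scoreable else StageLabel.W
    w = profile.band_weights[base_stage]
    amp = profile.amplitudes[base_stage]

    x = np.zeros(n)
    for weight, name in zip(w / w.sum(), _BAND_NAMES):
        if weight <= 0:
            continue
        lo, hi = BANDS[name]
        x += np.sqrt(weight) * _band_noise(rng, n, rate, lo, hi)

    if base_stage is StageLabel.N2:
        # amplitude-modulated 0.5-s sigma bursts: the spindle signature
        lo_sp, hi_sp = profile.n2_spindles_per_epoch
        n_spindles = int(rng.integers(lo_sp, hi_sp + 1))
        t = np.arange(n) / rate
        for _ in range(n_spindles):
            center = rng.uniform(1.0, 29.0)
            f = rng.uniform(12.0, 15.0)
            env = np.exp(-0.5 * ((t - center) / 0.25) ** 2)
            x += 1.2 * env * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))

    # 1/f background
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    with np.errstate(divide="ignore"):
        spec *= np.where(freqs > 0, freqs ** (-profile.background_exponent / 2.0), 0)
    bg = np.fft.irfft(spec, n=n)
    bg_rms = np.sqrt(np.mean(bg ** 2))
    if bg_rms > 0:
        f = profile.background_fraction
        x = np.sqrt(1 - f) * (x / np.sqrt(np.mean(x ** 2))) + np.sqrt(f) * (bg / bg_rms)

    if not stage.is_scoreable:  # movement/unscored: broadband contamination
        x = 0.5 * x + 1.5 * rng.standard_normal(n)

    return amp * x


def generate_record(config: SyntheticCohortConfig, subject: int,
                    record: int) -> tuple[SleepRecord, Hypnogram]:
    """Generate one record; stream keyed by (seed, subject, record)."""
    rng = _record_rng(config.seed, subject, record)
    labels = generate_hypnogram(config.model, config.epochs_per_record, rng)
    gain = float(np.exp(rng.normal(0.0, config.gain_jitter)))
    spe = int(round(30.0 * config.sampling_rate))
    samples = np.empty(config.epochs_per_record * spe)
    for e, stage in enumerate(labels):
        samples[e * spe:(e + 1) * spe] = synthesize_epoch(
            config.profile, stage, config.sampling_rate, rng) * gain
    rec = SleepRecord(
        subject_id=f"S{subject:03d}", record_id=f"S{subject:03d}R{record}",
        channel_name="EEG Fpz-Cz", samples=samples,
        sampling_rate=config.sampling_rate)
    return rec, Hypnogram(list(labels))


def generate_cohort(config: SyntheticCohortConfig,
                    out_dir: str | Path | None = None,
                    ) -> list[tuple[SleepRecord, Hypnogram]]:
    """Generate the full cohort; optionally write EDF + CSV fixture files."""
    cohort = [
        generate_record(config, s, r)
        for s in range(config.n_subjects)
        for r in range(config.records_per_subject)
    ]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, hyp in cohort:
            write_edf(out / f"{rec.record_id}.edf", rec)
            write_hypnogram_csv(out / f"{rec.record_id}.csv", hyp)
    return cohort
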