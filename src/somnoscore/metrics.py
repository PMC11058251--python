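"""Confusion-matrix metrics, kappa agreement statistics and subject-wise CV.

Per-class precision/recall/F1 and the overall summaries (ACC, macro-F1,
average precision APR, average recall ARC) are computed from a pooled 5x5
confusion matrix (rows = reference stage, columns = prediction, order W, N1,
N2, N3, REM).  Cohen's kappa comes with its large-sample (Fleiss-Cohen-
Everitt) variance for the 95% CI and a two-tailed z-test of H0: kappa = 0;
Fleiss' kappa (>= 3 raters) uses the 1971 large-sample SE.  Agreement bands
follow McHugh: None (<= .20), Minimal (.21-.39), Weak (.40-.59), Moderate
(.60-.79), Strong (.80-.90), Almost Perfect (> .90).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import norm

from .stages import STAGE_NAMES, StageLabel

K = 5


class NoEvaluableEpochsError(ValueError):
    """Confusion matrix is empty: nothing to score."""


@dataclass
class ConfusionMatrix:
    """5x5 counts; rows = reference, columns = predicted."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((K, K), dtype=np.int64))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (K, K) or (self.counts < 0).any():
            raise ValueError("counts must be 5x5 nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion(reference: list[StageLabel], predicted: list[StageLabel],
              eval_mask: np.ndarray | None = None) -> ConfusionMatrix:
    """Count epochs where the mask is True and the reference is scoreable."""
    if len(reference) != len(predicted):
        raise ValueError("reference/predicted length mismatch")
    if eval_mask is None:
        eval_mask = np.ones(len(reference), dtype=bool)
    cm = np.zeros((K, K), dtype=np.int64)
    for ref, pred, ok in zip(reference, predicted, eval_mask):
        if ok and ref.is_scoreable and pred.is_scoreable:
            cm[ref.value, pred.value] += 1
    return ConfusionMatrix(cm)


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    kind: str  # "cohen" | "fleiss"
    se: float = float("nan")


class AgreementCategory(Enum):
    NONE = "None"
    MINIMAL = "Minimal"
    WEAK = "Weak"
    MODERATE = "Moderate"
    STRONG = "Strong"
    ALMOST_PERFECT = "AlmostPerfect"


@dataclass
class EvaluationReport:
    """Pooled confusion matrix with per-class and overall metrics (in %)."""

    confusion: ConfusionMatrix
    precision: np.ndarray  # (5,) %
    recall: np.ndarray     # (5,) %
    f1: np.ndarray         # (5,) %
    acc: float             # %
    mf1: float             # %
    apr: float             # %
    arc: float             # %
    kappa: KappaResult

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.counts.tolist(),
            "per_class": {
                name: {"precision": float(self.precision[i]),
                       "recall": float(self.recall[i]),
                       "f1": float(self.f1[i])}
                for i, name in enumerate(STAGE_NAMES)
            },
            "overall": {"ACC": self.acc, "MF1": self.mf1,
                        "APR": self.apr, "ARC": self.arc},
            "kappa": {"kappa": self.kappa.kappa, "ci_low": self.kappa.ci_low,
                      "ci_high": self.kappa.ci_high, "z": self.kappa.z,
                      "p_value": self.kappa.p_value, "kind": self.kappa.kind,
                      "category": mchugh_category(self.kappa.kappa).value},
        }


def report(cm: ConfusionMatrix) -> EvaluationReport:
    """Per-class P/R/F1 plus ACC/MF1/APR/ARC and Cohen's kappa.

    0/0 conventions resolve to 0 with a warning; the macro averages always
    run over all five stages.
    """
    if cm.total == 0:
        raise NoEvaluableEpochsError("no evaluable epochs")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    if (col == 0).any() or (row == 0).any():
        absent = [STAGE_NAMES[i] for i in range(K) if col[i] == 0 or row[i] == 0]
        warnings.warn(f"undefined precision/recall set to 0 for: {absent}",
                      stacklevel=2)
    acc = float(tp.sum() / cm.total)
    return EvaluationReport(
        confusion=cm,
        precision=precision * 100, recall=recall * 100, f1=f1 * 100,
        acc=acc * 100, mf1=float(f1.mean()) * 100,
        apr=float(precision.mean()) * 100, arc=float(recall.mean()) * 100,
        kappa=cohen_kappa(cm),
    )


def cohen_kappa(cm: ConfusionMatrix, alpha: float = 0.05) -> KappaResult:
    """Cohen's kappa with large-sample CI and two-tailed z-test.

    The CI uses the Fleiss-Cohen-Everitt asymptotic variance of kappa-hat;
    the z statistic uses the variance under H0: kappa = 0.
    """
    n = cm.total
    if n == 0:
        raise NoEvaluableEpochsError("no evaluable epochs")
    p = cm.counts.astype(float) / n
    prow = p.sum(axis=1)
    pcol = p.sum(axis=0)
    po = float(np.diag(p).sum())
    pe = float(prow @ pcol)
    if pe >= 1.0 - 1e-15:
        raise ValueError("degenerate marginals: chance agreement is 1")
    kappa = (po - pe) / (1 - pe)

    # Fleiss, Cohen & Everitt (1969) asymptotic variance of kappa-hat
    s1 = float(sum(p[i, i] * ((1 - pe) - (pcol[i] + prow[i]) * (1 - po)) ** 2
                   for i in range(K)))
    s2 = float(sum(p[i, j] * (pcol[i] + prow[j]) ** 2
                   for i in range(K) for j in range(K) if i != j))
    var = (s1 + (1 - po) ** 2 * s2 - (po * pe - 2 * pe + po) ** 2) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))

    # variance under H0 (kappa = 0) for the z-test
    var0 = (pe + pe ** 2 - float(sum(prow[i] * pcol[i] * (prow[i] + pcol[i])
                                     for i in range(K)))) / (n * (1 - pe) ** 2)
    se0 = float(np.sqrt(max(var0, 1e-300)))
    z = kappa / se0
    p_value = float(2 * norm.sf(abs(z)))
    zc = norm.ppf(1 - alpha / 2)
    return KappaResult(kappa=float(kappa), ci_low=float(kappa - zc * se),
                       ci_high=float(kappa + zc * se), z=float(z),
                       p_value=p_value, kind="cohen", se=se)


def fleiss_kappa(ratings: np.ndarray, n_raters: int | None = None,
                 alpha: float = 0.05) -> KappaResult:
    """Fleiss' kappa (1971) for >= 2 raters from an items x categories table.

    ``ratings[i, j]`` is the number of raters assigning category j to item i;
    every row must sum to the same rater count.  CI and z use the Fleiss 1971
    large-sample standard error.
    """
    ratings = np.asarray(ratings, dtype=float)
    row_sums = ratings.sum(axis=1)
    if n_raters is None:
        n_raters = int(row_sums[0])
    if not np.all(row_sums == n_raters):
        raise ValueError("all items must have the same number of raters")
    N, _ = ratings.shape
    n = n_raters
    pj = ratings.sum(axis=0) / (N * n)
    Pi = (np.sum(ratings ** 2, axis=1) - n) / (n * (n - 1))
    Pbar = float(Pi.mean())
    Pe = float(np.sum(pj ** 2))
    if Pe >= 1.0 - 1e-15:
        raise ValueError("degenerate marginals: chance agreement is 1")
    kappa = (Pbar - Pe) / (1 - Pe)

    # Fleiss 1971 large-sample SE
    q = pj * (1 - pj)
    sq = float(q.sum())
    num = sq ** 2 - float(np.sum(q * (1 - 2 * pj)))
    se = float(np.sqrt(2.0 / (N * n * (n - 1))) * np.sqrt(max(num, 0.0)) / sq)
    z = kappa / se if se > 0 else float("inf")
    p_value = float(2 * norm.sf(abs(z)))
    zc = norm.ppf(1 - alpha / 2)
    return KappaResult(kappa=float(kappa), ci_low=float(kappa - zc * se),
                       ci_high=float(kappa + zc * se), z=float(z),
                       p_value=p_value, kind="fleiss", se=se)


def mchugh_category(kappa: float) -> AgreementCategory:
    """McHugh agreement band for a kappa value (negatives count as None)."""
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa < 0.21:
        return AgreementCategory.NONE
    if kappa < 0.40:
        return AgreementCategory.MINIMAL
    if kappa < 0.60:
        return AgreementCategory.WEAK
    if kappa < 0.80:
        return AgreementCategory.MODERATE
    if kappa <= 0.90:
        return AgreementCategory.STRONG
    return AgreementCategory.ALMOST_PERFECT


def subject_wise_folds(subject_ids: list[str], k: int,
                       seed: int = 0) -> dict[str, int]:
    """Assign subjects to k folds; all of a subject's recordings share a fold.

    With k equal to the number of subjects this is leave-one-subject-out;
    otherwise subjects are round-robined after a seeded shuffle, giving fold
    sizes that differ by at most one.
    """
    subjects = sorted(set(subject_ids))
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    return {subj: i % k for i, subj in enumerate(order)}
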