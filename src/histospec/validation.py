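"""Monte Carlo cross-validation and multi-class performance measures.

The classifier is validated by repeated random splitting of the reference
collection at a fixed ratio (default 0.9 train / 0.1 test, 20 pairs).  The
correct and wrong predictions of every train/test pair are pooled into one
confusion matrix, from which all measures derive:

* per class k (one-vs-rest): sensitivity TP/(TP+FN), specificity TN/(TN+FP),
  precision TP/(TP+FP);
* overall: total accuracy c/s; Cohen's kappa (p_o - p_e)/(1 - p_e) with
  chance agreement p_e from the row/column marginals; and the extended
  (multi-class) Matthews correlation coefficient
  (c*s - Σ_k r_k*c_k) / sqrt((s² - Σ c_k²)(s² - Σ r_k²)).

Measures with a zero denominator are flagged undefined (NaN plus a flag),
never silently reported as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .hyperdata import CLASS_NAMES, ReferenceCollection, ValidationError

__all__ = [
    "ValidationConfig",
    "ConfusionMatrix",
    "ClassMetrics",
    "OverallMetrics",
    "CrossValidationResults",
    "class_metrics",
    "overall_metrics",
    "monte_carlo_cv",
]

logger = logging.getLogger(__name__)

_UNDEF = float("nan")


@dataclass(frozen=True)
class ValidationConfig:
    """Monte Carlo CV settings: split ratio, number of pairs, stratification."""

    splitting_ratio: float = 0.9
    n_pairs: int = 20
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.splitting_ratio < 1.0:
            raise ValidationError("splitting_ratio must lie in (0, 1)")
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be at least 1")


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_ids)
        if self.counts.shape != (k, k):
            raise ValidationError("confusion matrix must be K x K")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be nonnegative")

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray,
                    class_ids: tuple[int, ...]) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(class_ids)}
        k = len(class_ids)
        counts = np.zeros((k, k), dtype=int)
        for t, p in zip(np.asarray(y_true).ravel(), np.asarray(y_pred).ravel()):
            counts[idx[int(t)], idx[int(p)]] += 1
        return cls(counts, tuple(class_ids))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))


@dataclass
class ClassMetrics:
    """Per-class one-vs-rest sensitivity, specificity and precision.

    Values are NaN where the defining denominator is zero; the matching entry
    of ``defined`` is then False.
    """

    class_ids: tuple[int, ...]
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    defined: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class OverallMetrics:
    """Total accuracy, Cohen's kappa and the extended Matthews correlation."""

    total_accuracy: float
    cohens_kappa: float
    extended_mcc: float
    defined: dict[str, bool] = field(default_factory=dict)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return _UNDEF, False
    return num / den, True


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest sensitivity/specificity/precision for every class."""
    c = cm.counts.astype(float)
    s = c.sum()
    tp = np.diag(c)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = s - tp - fn - fp
    k = len(cm.class_ids)
    sens = np.empty(k)
    spec = np.empty(k)
    prec = np.empty(k)
    dflags = {"sensitivity": np.ones(k, bool), "specificity": np.ones(k, bool),
              "precision": np.ones(k, bool)}
    for i in range(k):
        sens[i], dflags["sensitivity"][i] = _safe_div(tp[i], tp[i] + fn[i])
        spec[i], dflags["specificity"][i] = _safe_div(tn[i], tn[i] + fp[i])
        prec[i], dflags["precision"][i] = _safe_div(tp[i], tp[i] + fp[i])
    return ClassMetrics(cm.class_ids, sens, spec, prec, dflags)


def overall_metrics(cm: ConfusionMatrix) -> OverallMetrics:
    """Accuracy, Cohen's kappa and extended MCC from one confusion matrix."""
    s = cm.total
    if s == 0:
        raise ValidationError("empty confusion matrix")
    c = cm.correct
    rows = cm.counts.sum(axis=1).astype(float)
    cols = cm.counts.sum(axis=0).astype(float)
    acc = c / s
    p_e = float(rows @ cols) / (s * s)
    kappa, kappa_ok = _safe_div(acc - p_e, 1.0 - p_e)
    mcc_num = c * s - float(rows @ cols)
    mcc_den = math.sqrt((s * s - float(cols @ cols)) * (s * s - float(rows @ rows)))
    mcc, mcc_ok = _safe_div(mcc_num, mcc_den)
    return OverallMetrics(acc, kappa, mcc,
                          {"cohens_kappa": kappa_ok, "extended_mcc": mcc_ok})


@dataclass
class CrossValidationResults:
    """Pooled Monte Carlo CV outcome with per-split diagnostics.

    ``summary()`` renders the per-class measures and the overall footer as a
    plain-text table.
    """

    confusion: ConfusionMatrix
    per_class: ClassMetrics
    overall: OverallMetrics
    per_split_accuracy: list[float]
    config: ValidationConfig
    n_resampled_splits: int = 0

    def summary(self) -> str:
        lines = ["Monte Carlo cross-validation "
                 f"(ratio {self.config.splitting_ratio}, {self.config.n_pairs} pairs, "
                 f"{self.confusion.total} pooled predictions)"]
        lines.append(f"{'class':<18}{'sensitivity':>12}{'specificity':>12}{'precision':>12}")
        for i, cid in enumerate(self.per_class.class_ids):
            name = CLASS_NAMES.get(cid, str(cid))
            lines.append(f"{name:<18}"
                         f"{self.per_class.sensitivity[i]:>12.4f}"
                         f"{self.per_class.specificity[i]:>12.4f}"
                         f"{self.per_class.precision[i]:>12.4f}")
        o = self.overall
        lines.append(f"{'total accuracy':<18}{o.total_accuracy:>12.4f}")
        lines.append(f"{'Cohen kappa':<18}{o.cohens_kappa:>12.4f}")
        lines.append(f"{'extended MCC':<18}{o.extended_mcc:>12.4f}")
        return "\n".join(lines)


def _split_indices(labels: np.ndarray, ratio: float, stratified: bool,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = labels.size
    if stratified:
        train_idx: list[int] = []
        test_idx: list[int] = []
        for cls in np.unique(labels):
            idx = np.nonzero(labels == cls)[0]
            perm = rng.permutation(idx)
            n_train = int(round(ratio * idx.size))
            train_idx.extend(perm[:n_train])
            test_idx.extend(perm[n_train:])
        return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))
    perm = rng.permutation(n)
    n_train = int(round(ratio * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def monte_carlo_cv(refs: ReferenceCollection, bank, rdf_config=None,
                   vconfig: ValidationConfig | None = None) -> CrossValidationResults:
    """Monte Carlo cross-validation of the forest classifier.

    For each of ``n_pairs`` seeded random splits a fresh forest is trained on
    the train fraction and applied to the test fraction; the correct and
    wrong predictions of all pairs are pooled into one confusion matrix from
    which the class-specific and overall measures are computed.  A split
    whose training half misses a class is resampled (logged), up to 10
    attempts.
    """
    from .classify import RdfConfig, TissueClassifier
    from .descriptors import compute_descriptors

    vcfg = vconfig or ValidationConfig()
    rcfg = rdf_config or RdfConfig()
    labels = refs.labels()
    class_ids = tuple(sorted(np.unique(labels).tolist()))
    if len(class_ids) < 2:
        raise ValidationError("cross-validation needs at least two classes")
    feat = compute_descriptors(refs, bank).values
    rng = np.random.default_rng(vcfg.seed)
    k = len(class_ids)
    pooled = np.zeros((k, k), dtype=int)
    per_split_acc: list[float] = []
    n_resampled = 0
    for pair in range(vcfg.n_pairs):
        for attempt in range(10):
            tr, te = _split_indices(labels, vcfg.splitting_ratio, vcfg.stratified, rng)
            if te.size and np.unique(labels[tr]).size == len(class_ids):
                break
            n_resampled += 1
            logger.warning("split %d attempt %d missing a class; resampling",
                           pair, attempt)
        else:
            raise ValidationError(
                f"could not draw a split containing every class (pair {pair})")
        clf = TissueClassifier.from_matrix(feat[tr], labels[tr],
                                           RdfConfig(rcfg.n_trees, rcfg.max_features,
                                                     rcfg.seed + pair, rcfg.min_leaf))
        res = clf.fit()
        pred = res.predict_matrix(feat[te])
        cmp_ = ConfusionMatrix.from_labels(labels[te], pred, class_ids)
        pooled += cmp_.counts
        per_split_acc.append(cmp_.correct / cmp_.total)
    cm = ConfusionMatrix(pooled, class_ids)
    return CrossValidationResults(cm, class_metrics(cm), overall_metrics(cm),
                                  per_split_acc, vcfg, n_resampled)
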