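"""Random-decision-forest tissue classification of FTIR hyperspectral images.

The central modelling object follows the Model/Results convention:
:class:`TissueClassifier` is built from a labelled reference collection and a
descriptor bank; ``fit()`` returns a :class:`TissueClassifierResults` that
carries the fitted forest, training diagnostics, whole-image classification
and a ``summary()`` table.  Monte Carlo cross-validation of the same design
is available as :meth:`TissueClassifier.monte_carlo_cv`.

Variable reduction follows the forest's own variable-importance measure
(Breiman's mean decrease in impurity): the lowest-importance fraction of
descriptors is dropped and the forest refitted, iterating until a target
count is reached or the out-of-bag score degrades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .descriptors import DescriptorBank, compute_descriptors
from .hyperdata import (
    CLASS_COLORS,
    HyperspectralImage,
    ReferenceCollection,
    TissueClassMap,
    ValidationError,
)

__all__ = [
    "RdfConfig",
    "ReductionConfig",
    "ReductionTrace",
    "TissueClassifier",
    "TissueClassifierResults",
    "reduce_variables",
    "render_overlay",
    "save_classifier",
    "load_classifier",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RdfConfig:
    """Forest hyperparameters: tree count, feature subsampling, seed."""

    n_trees: int = 200
    max_features: float | str = "sqrt"
    seed: int = 0
    min_leaf: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be at least 1")


@dataclass(frozen=True)
class ReductionConfig:
    """Iterative importance-driven variable elimination settings."""

    drop_fraction_per_iter: float = 0.2
    stop_n: int = 215
    max_iters: int = 50
    oob_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.drop_fraction_per_iter < 1.0:
            raise ValidationError("drop_fraction_per_iter must lie in (0, 1)")
        if self.stop_n < 1:
            raise ValidationError("stop_n must be at least 1")


@dataclass
class ReductionTrace:
    """Per-iteration record: (n_variables, oob_score, dropped variable ids)."""

    iterations: list[tuple[int, float, list[int]]] = field(default_factory=list)

    def n_variables(self) -> list[int]:
        return [n for n, _, _ in self.iterations]

    def oob_scores(self) -> list[float]:
        return [s for _, s, _ in self.iterations]


class TissueClassifier:
    """Forest tissue-classification model over a reference design.

    Parameters
    ----------
    refs : ReferenceCollection, optional
        Labelled training spectra; the design matrix is computed from them
        through ``bank``.
    bank : DescriptorBank, optional
        Feature definition.  Required when constructing from a reference
        collection or when classifying whole images.
    config : RdfConfig
        Forest hyperparameters.
    """

    def __init__(self, refs: ReferenceCollection | None = None,
                 bank: DescriptorBank | None = None,
                 config: RdfConfig | None = None,
                 _X: np.ndarray | None = None,
                 _y: np.ndarray | None = None):
        self.config = config or RdfConfig()
        self.bank = bank
        self.refs = refs
        if refs is not None:
            if bank is None:
                raise ValidationError("a descriptor bank is required with references")
            dm = compute_descriptors(refs, bank)
            self._X, self._y = dm.values, refs.labels()
        elif _X is not None and _y is not None:
            self._X = np.asarray(_X, dtype=float)
            self._y = np.asarray(_y, dtype=int)
        else:
            raise ValidationError("provide either references+bank or a feature matrix")
        classes, counts = np.unique(self._y, return_counts=True)
        if classes.size < 2:
            raise ValidationError("training data must contain at least two classes")
        if counts.min() < 2:
            raise ValidationError("every class needs at least two training spectra")
        self.class_ids: tuple[int, ...] = tuple(int(c) for c in classes)
        self.class_counts: dict[int, int] = {int(c): int(n)
                                             for c, n in zip(classes, counts)}

    @classmethod
    def from_matrix(cls, X: np.ndarray, y: np.ndarray,
                    config: RdfConfig | None = None,
                    bank: DescriptorBank | None = None) -> "TissueClassifier":
        """Build the model directly from a precomputed feature matrix."""
        return cls(config=config, bank=bank, _X=X, _y=y)

    def _make_forest(self, oob: bool = False) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.config.n_trees,
            max_features=self.config.max_features,
            min_samples_leaf=self.config.min_leaf,
            oob_score=oob,
            random_state=self.config.seed,
            n_jobs=1,
        )

    def fit(self, oob: bool = False) -> "TissueClassifierResults":
        """Fit the forest; deterministic for a given config seed."""
        forest = self._make_forest(oob=oob)
        forest.fit(self._X, self._y)
        return TissueClassifierResults(self, forest)

    def monte_carlo_cv(self, vconfig=None):
        """Monte Carlo CV of this design; see :func:`histospec.validation.monte_carlo_cv`."""
        from .validation import CrossValidationResults, monte_carlo_cv  # noqa: F401

        if self.refs is None or self.bank is None:
            raise ValidationError("cross-validation needs references and a bank")
        return monte_carlo_cv(self.refs, self.bank, self.config, vconfig)


class TissueClassifierResults:
    """Fitted-forest results: predictions, image classification, diagnostics."""

    def __init__(self, model: TissueClassifier, forest: RandomForestClassifier):
        self.model = model
        self.forest = forest
        self.training_accuracy = float(forest.score(model._X, model._y))
        self.oob_score = float(getattr(forest, "oob_score_", float("nan")))
        self.feature_importances = np.asarray(forest.feature_importances_)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Majority-vote class per row; probability ties resolve to the lower id."""
        proba = self.forest.predict_proba(np.asarray(X, dtype=float))
        # argmax takes the first maximum; classes_ is sorted ascending, so
        # ties break toward the lower class id.
        return self.forest.classes_[np.argmax(proba, axis=1)].astype(int)

    def classify_image(self, img: HyperspectralImage) -> TissueClassMap:
        """Classify every pixel of a cube into a tissue class map."""
        if self.model.bank is None:
            raise ValidationError("image classification needs the descriptor bank")
        if self.model.refs is not None and not (img.axis == self.model.refs.axis):
            raise ValidationError("image axis does not match the training axis")
        feat = compute_descriptors(img, self.model.bank).values
        labels = self.predict_matrix(feat).reshape(img.shape)
        return TissueClassMap(labels, pixel_size_um=img.pixel_size_um,
                              origin_um=img.origin_um)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Random-decision-forest tissue classifier",
            f"  trees: {cfg.n_trees}   max_features: {cfg.max_features}   seed: {cfg.seed}",
            f"  features: {self.model._X.shape[1]}   "
            f"training spectra: {self.model._X.shape[0]}",
            "  per-class counts: " + ", ".join(
                f"{cid}:{n}" for cid, n in self.model.class_counts.items()),
            f"  resubstitution accuracy: {self.training_accuracy:.4f}",
        ]
        if np.isfinite(self.oob_score):
            lines.append(f"  out-of-bag accuracy: {self.oob_score:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Importance-driven variable reduction
# ---------------------------------------------------------------------------


def reduce_variables(refs: ReferenceCollection, bank: DescriptorBank,
                     rcfg: ReductionConfig | None = None,
                     cfg: RdfConfig | None = None,
                     ) -> tuple[DescriptorBank, ReductionTrace]:
    """Iteratively drop the least important descriptors.

    Each iteration fits the forest with out-of-bag scoring, ranks the active
    descriptors by mean decrease in impurity and drops the lowest
    ``drop_fraction_per_iter`` (the final drop is clamped to land exactly on
    ``stop_n``).  Iteration stops once ``n <= stop_n`` or once the out-of-bag
    score falls more than ``oob_tolerance`` below its running best.  The
    returned bank is the smallest whose out-of-bag score stays within
    ``oob_tolerance`` of the best seen (parsimony rule); the full trace is
    returned alongside.
    """
    rcfg = rcfg or ReductionConfig()
    cfg = cfg or RdfConfig()
    if rcfg.stop_n >= bank.n:
        raise ValidationError(
            f"stop_n={rcfg.stop_n} must be smaller than the bank size {bank.n}")
    dm = compute_descriptors(refs, bank)
    X, y = dm.values, refs.labels()
    active = np.arange(bank.n)
    trace = ReductionTrace()
    candidates: list[tuple[int, float, np.ndarray]] = []
    for _ in range(rcfg.max_iters):
        model = TissueClassifier.from_matrix(X[:, active], y, cfg)
        res = model.fit(oob=True)
        oob = res.oob_score
        candidates.append((active.size, oob, active.copy()))
        best = max(c[1] for c in candidates)
        logger.info("reduction: %d variables, oob %.4f", active.size, oob)
        if active.size <= rcfg.stop_n:
            trace.iterations.append((int(active.size), oob, []))
            break
        if oob < best - rcfg.oob_tolerance:
            trace.iterations.append((int(active.size), oob, []))
            break
        n_drop = max(1, int(np.floor(rcfg.drop_fraction_per_iter * active.size)))
        n_drop = min(n_drop, active.size - rcfg.stop_n)
        order = np.argsort(res.feature_importances, kind="stable")
        dropped = active[order[:n_drop]]
        trace.iterations.append((int(active.size), oob, [int(i) for i in dropped]))
        keep = np.ones(active.size, dtype=bool)
        keep[order[:n_drop]] = False
        active = active[keep]
    best_oob = max(c[1] for c in candidates)
    admissible = [c for c in candidates if c[1] >= best_oob - rcfg.oob_tolerance]
    _, _, chosen = min(admissible, key=lambda c: c[0])
    return bank.subset(np.sort(chosen)), trace


# ---------------------------------------------------------------------------
# Overlay rendering and model persistence
# ---------------------------------------------------------------------------


def render_overlay(img: HyperspectralImage, cmap: TissueClassMap,
                   alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend class colours over a mean-absorbance grayscale image.

    ``alpha=0`` yields the grayscale alone, ``alpha=1`` the pure class
    colours.  Returns an (rows, cols, 3) float array in [0, 1].
    """
    if img.shape != cmap.shape:
        raise ValidationError("image and class map shapes differ")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    mean_abs = img.data.mean(axis=2)
    lo, hi = mean_abs.min(), mean_abs.max()
    gray = (mean_abs - lo) / (hi - lo) if hi > lo else np.zeros_like(mean_abs)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    colors = np.zeros_like(rgb)
    for cid, col in CLASS_COLORS.items():
        colors[cmap.labels == cid] = col
    return (1.0 - alpha) * rgb + alpha * colors


def save_classifier(results: TissueClassifierResults, path: str) -> str:
    """Persist a fitted classifier (forest + bank + meta) to one archive."""
    payload = {
        "forest": results.forest,
        "bank": results.model.bank,
        "config": results.model.config,
        "class_ids": results.model.class_ids,
        "class_counts": results.model.class_counts,
        "X_shape": results.model._X.shape,
    }
    joblib.dump(payload, path)
    return path


def load_classifier(path: str) -> TissueClassifierResults:
    payload = joblib.load(path)
    model = TissueClassifier.__new__(TissueClassifier)
    model.config = payload["config"]
    model.bank = payload["bank"]
    model.refs = None
    model.class_ids = payload["class_ids"]
    model.class_counts = payload["class_counts"]
    model._X = np.zeros(payload["X_shape"])
    model._y = np.zeros(payload["X_shape"][0], dtype=int)
    res = TissueClassifierResults.__new__(TissueClassifierResults)
    res.model = model
    res.forest = payload["forest"]
    res.training_accuracy = float("nan")
    res.oob_score = float("nan")
    res.feature_importances = np.asarray(payload["forest"].feature_importances_)
    return res
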