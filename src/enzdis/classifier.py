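"""Per-category maximum-margin sentence classifiers and confidence tiers.

Each relation category — causal interaction, ongoing research, diagnostic
usage, therapeutic application — gets its own binary soft-margin SVM
trained on a balanced set: all units positively annotated for the category
joined with an equal-size random sample of negatively annotated units that
still contain an enzyme-disease co-occurrence. Categories are
non-exclusive, so a unit can be positive for several models at once.

A parameter grid over the four standard kernels is ranked by
cross-validated F1; the survivors (precision >= 0.7 and F1 >= 0.5 in at
least one category) form a per-category ensemble whose agreement fraction
is mapped onto a four-level confidence scheme: the higher the fraction of
models voting positive, the higher the tier, with precision and
specificity descending from level 4 to level 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .cooccur import CooccurrenceRecord
from .evaluation import CVResult, cross_validate
from .features import REMOVAL, REPLACEMENT, PreprocessMode, TfidfUnitVectorizer, preprocess_unit

logger = logging.getLogger(__name__)

CATEGORIES = (
    "causal_interaction",
    "ongoing_research",
    "diagnostic_usage",
    "therapeutic_application",
)

UNASSIGNED = 0

_KERNEL_MAP = {
    "linear": "linear",
    "polynomial": "poly",
    "radial_basis": "rbf",
    "sigmoid": "sigmoid",
}


@dataclass(frozen=True)
class ModelParams:
    """One SVM configuration: kernel, cost and kernel-specific parameters."""

    kernel: str = "linear"
    cost: float = 1.0
    degree: int = 3
    gamma: float = 1.0
    coef0: float = 0.0
    mode: str = REMOVAL

    def __post_init__(self) -> None:
        if self.kernel not in _KERNEL_MAP:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.mode not in (REMOVAL, REPLACEMENT):
            raise ValueError(f"unknown preprocess mode {self.mode!r}")


def default_grid(modes: Sequence[str] = (REMOVAL, REPLACEMENT)) -> list[ModelParams]:
    """A desk-scale grid spanning all four kernels, costs and kernel params."""
    grid: list[ModelParams] = []
    for mode in modes:
        for cost in (0.1, 1.0, 10.0):
            grid.append(ModelParams("linear", cost, mode=mode))
            for gamma in (0.1, 1.0):
                grid.append(ModelParams("radial_basis", cost, gamma=gamma, mode=mode))
                for coef0 in (0.0, 1.0):
                    grid.append(ModelParams("sigmoid", cost, gamma=gamma,
                                            coef0=coef0, mode=mode))
                    for degree in (2, 3):
                        grid.append(ModelParams("polynomial", cost, degree=degree,
                                                gamma=gamma, coef0=coef0, mode=mode))
    return grid


def make_category_pipeline(params: ModelParams) -> Pipeline:
    """tf-idf vectorizer + SVC pipeline operating on token sequences."""
    svc = SVC(
        kernel=_KERNEL_MAP[params.kernel],
        C=params.cost,
        degree=params.degree,
        gamma=params.gamma,
        coef0=params.coef0,
    )
    return Pipeline([("tfidf", TfidfUnitVectorizer()), ("svm", svc)])


def train_binary(
    X: Sequence[Sequence[str]], y: Sequence[int], params: ModelParams
) -> Pipeline:
    """Fit one binary SVM on tokenized units; both labels must be present."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    pipe = make_category_pipeline(params)
    pipe.fit(list(X), y)
    return pipe


def make_balanced_set(
    units: Sequence,
    labels: Sequence[frozenset | set],
    category: str,
    seed: int,
    eligible: Sequence[bool] | None = None,
) -> tuple[list, np.ndarray]:
    """All positives for ``category`` plus an equal-size negative sample.

    Negatives are drawn uniformly (seeded, without replacement) from units
    not labelled with the category that still carry an enzyme-disease
    co-occurrence (``eligible``; all units by default). Output size is
    twice the positive count.
    """
    if eligible is None:
        eligible = [True] * len(units)
    pos_idx = [i for i, ls in enumerate(labels) if category in ls]
    neg_pool = [i for i, ls in enumerate(labels)
                if category not in ls and eligible[i]]
    if not pos_idx:
        raise ValueError(f"no positive units for category {category!r}")
    if len(neg_pool) < len(pos_idx):
        raise ValueError(
            f"category {category!r}: need {len(pos_idx)} eligible negatives, "
            f"only {len(neg_pool)} available (short by {len(pos_idx) - len(neg_pool)})"
        )
    rng = np.random.default_rng(seed)
    neg_idx = sorted(rng.choice(len(neg_pool), size=len(pos_idx), replace=False))
    chosen = pos_idx + [neg_pool[i] for i in neg_idx]
    y = np.array([1] * len(pos_idx) + [0] * len(pos_idx), dtype=int)
    return [units[i] for i in chosen], y


def _tokens_for_mode(records: Sequence[CooccurrenceRecord], mode: str) -> list[list[str]]:
    return [preprocess_unit(r, mode) for r in records]


def _fit_predict(params: ModelParams):
    def fn(X_train, y_train, X_test):
        pipe = train_binary(X_train, y_train, params)
        scores = pipe.decision_function(X_test)
        return (scores > 0).astype(int), scores
    return fn


def cross_validate_category(
    records: Sequence[CooccurrenceRecord],
    labels: Sequence[frozenset | set],
    category: str,
    params: ModelParams,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Balanced-set k-fold CV of one category under one parameter set."""
    units, y = make_balanced_set(records, labels, category, seed=seed)
    tokens = _tokens_for_mode(units, params.mode)
    return cross_validate(tokens, y, _fit_predict(params), k=k, seed=seed)


@dataclass
class GridEntry:
    params: ModelParams
    per_category: dict[str, CVResult]
    mean_f1: float
    survives: bool


def passes_selection(per_category: Mapping[str, CVResult],
                     min_precision: float = 0.7, min_f1: float = 0.5) -> bool:
    """Survival rule: precision >= 0.7 and F1 >= 0.5 in at least one category."""
    return any(
        cv.mean["precision"] >= min_precision and cv.mean["f1"] >= min_f1
        for cv in per_category.values()
    )


def grid_search(
    records: Sequence[CooccurrenceRecord],
    labels: Sequence[frozenset | set],
    grid: Sequence[ModelParams],
    k: int = 5,
    seed: int = 0,
    categories: Sequence[str] = CATEGORIES,
) -> list[GridEntry]:
    """Evaluate every parameter set by k-fold CV and rank by mean F1.

    Each entry carries per-category CV results and a ``survives`` flag
    implementing the model-reduction rule. An empty survivor set is a
    warning, not an error.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    entries: list[GridEntry] = []
    for params in grid:
        per_cat = {
            c: cross_validate_category(records, labels, c, params, k=k, seed=seed)
            for c in categories
        }
        mean_f1 = float(np.mean([cv.mean["f1"] for cv in per_cat.values()]))
        entries.append(GridEntry(params, per_cat, mean_f1, passes_selection(per_cat)))
    entries.sort(key=lambda e: e.mean_f1, reverse=True)
    if not any(e.survives for e in entries):
        logger.warning("no parameter set passed the precision/F1 selection filter")
    return entries


# ---------------------------------------------------------------------------
# ensembles and confidence


def ensemble_vote(models: Sequence[Pipeline], X: Sequence[Sequence[str]]) -> np.ndarray:
    """Fraction of models with a positive decision score, per unit."""
    if not models:
        raise ValueError("ensemble needs at least one model")
    votes = np.zeros(len(X), dtype=float)
    for m in models:
        votes += (m.decision_function(list(X)) > 0).astype(float)
    return votes / len(models)


@dataclass(frozen=True)
class ConfidenceScheme:
    """Vote-fraction thresholds for levels 4 down to 1 (strictly decreasing)."""

    thresholds: tuple[float, float, float, float] = (0.90, 0.70, 0.50, 0.25)

    def __post_init__(self) -> None:
        t = self.thresholds
        if not all(t[i] > t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("thresholds must be strictly decreasing from level 4 to 1")


def assign_confidence(vote: float, scheme: ConfidenceScheme = ConfidenceScheme()) -> int:
    """Highest level whose threshold the vote fraction reaches (else 0).

    Thresholds are inclusive; a vote below the level-1 threshold yields
    ``UNASSIGNED`` (0). Monotone by construction: a higher vote never maps
    to a lower level.
    """
    if not 0.0 <= vote <= 1.0:
        raise ValueError(f"vote fraction must be in [0, 1], got {vote}")
    for level, thr in zip((4, 3, 2, 1), scheme.thresholds):
        if vote >= thr:
            return level
    return UNASSIGNED


@dataclass
class CategoryEnsemble:
    """Fitted per-category model lists plus the confidence scheme.

    ``models[category]`` holds (params, fitted pipeline) pairs; preprocessing
    mode is taken from each model's own params so removal and replacement
    models can coexist in one ensemble.
    """

    models: dict[str, list[tuple[ModelParams, Pipeline]]]
    scheme: ConfidenceScheme = ConfidenceScheme()

    def vote_fractions(self, records: Sequence[CooccurrenceRecord],
                       category: str) -> np.ndarray:
        pairs = self.models[category]
        if not pairs:
            raise ValueError(f"no models for category {category!r}")
        votes = np.zeros(len(records), dtype=float)
        token_cache: dict[str, list[list[str]]] = {}
        for params, model in pairs:
            if params.mode not in token_cache:
                token_cache[params.mode] = _tokens_for_mode(records, params.mode)
            scores = model.decision_function(token_cache[params.mode])
            votes += (scores > 0).astype(float)
        return votes / len(pairs)

    def confidence_levels(self, records: Sequence[CooccurrenceRecord],
                          category: str) -> np.ndarray:
        return np.array([
            assign_confidence(v, self.scheme)
            for v in self.vote_fractions(records, category)
        ], dtype=int)

    def classify(self, records: Sequence[CooccurrenceRecord]) -> dict[str, np.ndarray]:
        """Per-category confidence level (0 = unassigned) for every record."""
        return {c: self.confidence_levels(records, c) for c in self.models}


def train_ensemble(
    records: Sequence[CooccurrenceRecord],
    labels: Sequence[frozenset | set],
    param_sets: Sequence[ModelParams],
    seed: int = 0,
    categories: Sequence[str] = CATEGORIES,
    scheme: ConfidenceScheme = ConfidenceScheme(),
) -> CategoryEnsemble:
    """Fit one model per (category, parameter set) on balanced training sets."""
    models: dict[str, list[tuple[ModelParams, Pipeline]]] = {}
    for category in categories:
        fitted: list[tuple[ModelParams, Pipeline]] = []
        units, y = make_balanced_set(records, labels, category, seed=seed)
        for params in param_sets:
            tokens = _tokens_for_mode(units, params.mode)
            fitted.append((params, train_binary(tokens, y, params)))
        models[category] = fitted
    return CategoryEnsemble(models=models, scheme=scheme)
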