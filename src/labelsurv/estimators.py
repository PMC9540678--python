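"""Plug-in conditional class-probability estimators.

Any estimator of ``P(y | x)`` can feed the set-valued classifier; the
reference implementation is an unregularized main-terms multinomial
logistic regression.  Random-forest and gradient-boosting adapters are
provided behind the same contract for users who want a nonparametric
plug-in; class-probability columns always follow sorted label order
``1..K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .cohort import Cohort
from .conformal import validate_probabilities

__all__ = ["ProbEstimator", "fit", "predict_proba", "available_estimators"]


@dataclass
class ProbEstimator:
    """A fitted conditional-probability model with its feature contract."""

    name: str
    model: Any
    feature_names: list[str]
    n_classes: int
    hyperparameters: dict = field(default_factory=dict)

    def predict_proba(self, features: np.ndarray, feature_names: list[str] | None = None) -> np.ndarray:
        return predict_proba(self, features, feature_names)


def _make_multinomial_logit(**kw) -> LogisticRegression:
    # Unregularized main-terms fit; lbfgs handles the multinomial link.
    params = {"C": np.inf, "solver": "lbfgs", "max_iter": 2000}
    params.update(kw)
    return LogisticRegression(**params)


def _make_random_forest(**kw) -> RandomForestClassifier:
    params = {"n_estimators": 500, "min_samples_leaf": 250, "random_state": 0}
    params.update(kw)
    return RandomForestClassifier(**params)


def _make_gradient_boosting(**kw) -> GradientBoostingClassifier:
    params = {"max_depth": 3, "learning_rate": 1.0, "n_estimators": 2, "random_state": 0}
    params.update(kw)
    return GradientBoostingClassifier(**params)


_REGISTRY: dict[str, Callable[..., Any]] = {
    "multinomial_logit": _make_multinomial_logit,
    "random_forest": _make_random_forest,
    "gradient_boosting": _make_gradient_boosting,
}


def available_estimators() -> list[str]:
    return sorted(_REGISTRY)


def fit(estimator_spec: str | dict, train: Cohort) -> ProbEstimator:
    """Fit a registered probability estimator on a labeled cohort.

    ``estimator_spec`` is either a registered name or a mapping
    ``{"name": ..., **hyperparameters}``.

    Raises
    ------
    ValueError
        For unknown estimator names, missing labels, or a class absent
        from the training data (the probability columns would not span
        ``1..K``).
    """
    if isinstance(estimator_spec, str):
        name, hyper = estimator_spec, {}
    else:
        spec = dict(estimator_spec)
        name = spec.pop("name")
        hyper = spec
    if name not in _REGISTRY:
        raise ValueError(f"unknown estimator {name!r}; available: {available_estimators()}")
    if train.labels is None:
        raise ValueError("training cohort must have labels")
    present = np.unique(train.labels)
    expected = np.arange(1, train.n_classes + 1)
    if not np.array_equal(present, expected):
        missing = sorted(int(y) for y in set(expected) - set(present))
        raise ValueError(f"degenerate design: classes {missing} absent from training data")
    model = _REGISTRY[name](**hyper)
    model.fit(train.features, train.labels)
    return ProbEstimator(
        name=name,
        model=model,
        feature_names=list(train.feature_names),
        n_classes=train.n_classes,
        hyperparameters=hyper,
    )


def predict_proba(
    model: ProbEstimator, features: np.ndarray, feature_names: list[str] | None = None
) -> np.ndarray:
    """Predict an ``(n, K)`` row-stochastic probability matrix.

    When ``feature_names`` is given it must match the training columns
    (order included); a mismatch raises naming the offending columns.
    """
    if feature_names is not None and list(feature_names) != model.feature_names:
        missing = [c for c in model.feature_names if c not in feature_names]
        extra = [c for c in feature_names if c not in model.feature_names]
        raise ValueError(
            f"feature columns do not match training: missing={missing}, extra={extra}"
        )
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} feature columns, got {features.shape}"
        )
    probs = model.model.predict_proba(features)
    if probs.shape[1] != model.n_classes:
        raise ValueError(
            f"estimator produced {probs.shape[1]} probability columns for "
            f"{model.n_classes} classes"
        )
    return validate_probabilities(probs)
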