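"""Single-output shallow baselines and tree-based sensor importance.

The shallow models consume raw per-time-step standardized sensor vectors
(one 10-dimensional sample per time step; no windowing): an RBF-kernel
support vector classifier (C=5, gamma=0.1) and regressor (C=10, gamma=0.1),
and random forests (100 trees / sqrt(n_features) for classification,
60 trees / log2(n_features) for regression).

Sensor importance follows the tree-based recipe: per subject, normalized
impurity importances from the forest classifier (alpha_c) and regressor
(alpha_r) are averaged elementwise into alpha, subject alphas are averaged
across the cohort, and channels are ranked by descending total importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.svm import SVC, SVR

__all__ = [
    "ShallowConfig",
    "ImportanceRanking",
    "fit_shallow",
    "compute_importance",
    "select_top_k",
]

logger = logging.getLogger(__name__)

MODEL_KINDS = ("svc", "svr", "rf_cls", "rf_reg")


@dataclass(frozen=True)
class ShallowConfig:
    """Hyperparameters of the four shallow baselines."""

    svc_c: float = 5.0
    svc_gamma: float = 0.1
    svr_c: float = 10.0
    svr_gamma: float = 0.1
    rf_cls_trees: int = 100
    rf_cls_max_features: str = "sqrt"
    rf_reg_trees: int = 60
    rf_reg_max_features: str = "log2"
    #: optional uniform subsample size for kernel models on large sets
    subsample: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.svc_c <= 0 or self.svr_c <= 0:
            raise ValueError("C must be positive")
        if self.svc_gamma <= 0 or self.svr_gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.rf_cls_trees < 1 or self.rf_reg_trees < 1:
            raise ValueError("forests need at least one tree")


def fit_shallow(model_kind: str, features: np.ndarray, targets: np.ndarray,
                config: ShallowConfig = ShallowConfig()):
    """Fit one shallow baseline; returns the fitted sklearn estimator.

    ``features`` is [n x d] (d = channel count), ``targets`` holds class
    labels for svc/rf_cls or angles for svr/rf_reg. Kernel models optionally
    train on a seeded uniform subsample (config.subsample) for speed, which
    is logged when used.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    features = np.asarray(features)
    targets = np.asarray(targets)
    if features.ndim != 2 or features.shape[0] != targets.shape[0]:
        raise ValueError("features must be [n x d] aligned with targets")
    if model_kind in ("svc", "rf_cls") and np.unique(targets).size < 2:
        raise ValueError("classification needs at least two classes")

    if model_kind in ("svc", "svr") and config.subsample is not None \
            and features.shape[0] > config.subsample:
        rng = np.random.default_rng(config.seed)
        idx = rng.choice(features.shape[0], config.subsample, replace=False)
        logger.info("kernel model subsampled %d of %d samples",
                    config.subsample, features.shape[0])
        features, targets = features[idx], targets[idx]

    if model_kind == "svc":
        model = SVC(kernel="rbf", C=config.svc_c, gamma=config.svc_gamma)
    elif model_kind == "svr":
        model = SVR(kernel="rbf", C=config.svr_c, gamma=config.svr_gamma)
    elif model_kind == "rf_cls":
        model = RandomForestClassifier(
            n_estimators=config.rf_cls_trees,
            max_features=config.rf_cls_max_features,
            random_state=config.seed,
        )
    else:
        model = RandomForestRegressor(
            n_estimators=config.rf_reg_trees,
            max_features=config.rf_reg_max_features,
            random_state=config.seed,
        )
    return model.fit(features, targets)


@dataclass(frozen=True)
class ImportanceRanking:
    """Per-channel importances and the descending channel ranking (1-based)."""

    alpha_c: np.ndarray
    alpha_r: np.ndarray
    alpha: np.ndarray
    ranking: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.alpha)
        if sorted(self.ranking) != list(range(1, n + 1)):
            raise ValueError("ranking must be a permutation of 1..n_channels")


def _normalize(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    return v / s if s > 0 else np.full_like(v, 1.0 / len(v))


def compute_importance(
    per_subject_data: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    config: ShallowConfig = ShallowConfig(),
    mode: str = "impurity",
) -> ImportanceRanking:
    """Tree-based per-channel importance averaged over subjects.

    ``per_subject_data`` is a list of (features [n x N], labels [n],
    angles [n]) triples, one per subject. mode="impurity" (default) uses
    mean-decrease-in-impurity importances; mode="permutation" uses seeded
    permutation importances on the training data. Each attribute's
    importances are normalized to sum to one before averaging; ties in the
    final ranking break toward the lower channel index.
    """
    if not per_subject_data:
        raise ValueError("no subjects")
    if mode not in ("impurity", "permutation"):
        raise ValueError(f"unknown importance mode {mode!r}")
    alphas_c, alphas_r = [], []
    for features, labels, angles in per_subject_data:
        if np.unique(labels).size < 2:
            raise ValueError("importance needs at least two classes per subject")
        cls = fit_shallow("rf_cls", features, labels, config)
        reg = fit_shallow("rf_reg", features, angles, config)
        if mode == "impurity":
            a_c = cls.feature_importances_
            a_r = reg.feature_importances_
        else:
            a_c = permutation_importance(
                cls, features, labels, n_repeats=5, random_state=config.seed
            ).importances_mean.clip(min=0.0)
            a_r = permutation_importance(
                reg, features, angles, n_repeats=5, random_state=config.seed
            ).importances_mean.clip(min=0.0)
        alphas_c.append(_normalize(np.asarray(a_c, dtype=float)))
        alphas_r.append(_normalize(np.asarray(a_r, dtype=float)))
    alpha_c = np.mean(alphas_c, axis=0)
    alpha_r = np.mean(alphas_r, axis=0)
    alpha = (alpha_c + alpha_r) / 2.0
    order = np.argsort(-alpha, kind="stable")
    return ImportanceRanking(
        alpha_c=alpha_c,
        alpha_r=alpha_r,
        alpha=alpha,
        ranking=tuple(int(i) + 1 for i in order),
    )


def select_top_k(ranking: ImportanceRanking, k: int) -> tuple[int, ...]:
    """First k channels (1-based original indices) of the descending ranking."""
    n = len(ranking.ranking)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    return ranking.ranking[:k]
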