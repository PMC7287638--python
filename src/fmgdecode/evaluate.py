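"""Leave-one-trial-out evaluation, metrics and the ablation driver.

For each subject, every trial serves once as the test set while the
remaining trials train the model (leave-one-trial-out cross-validation).
Standardization statistics — and, in the strict ablation mode, sensor
importances — are fitted inside each fold's training split only. Per-subject
scores are unweighted means over folds; the cohort summary is the mean and
standard deviation across subjects.

Model comparison across subjects uses the Wilcoxon signed-rank test with the
exact null distribution (all 2^m sign assignments, computed by dynamic
programming over the rank-sum generating function) for m <= 25 paired
subjects, and a tie-corrected normal approximation beyond; zero differences
are dropped per the classic procedure, with the count recorded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .augment import (
    Arrangement,
    build_arrangement,
    fit_standardizer,
    make_image_dataset,
    standardize_trial,
)
from .models import DualModelConfig, build_model, predict, train
from .shallow import ImportanceRanking, ShallowConfig, fit_shallow, select_top_k
from .simulate import TrialRecording

__all__ = [
    "FoldResult",
    "CVResult",
    "ComparisonResult",
    "DegenerateTestError",
    "DualNetSpec",
    "ShallowSpec",
    "loto_folds",
    "accuracy",
    "r_squared",
    "confusion",
    "paired_nonparametric_test",
    "run_experiment",
    "sensor_ablation",
    "sensor_ablation_strict",
    "restrict_channels",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Fraction of correctly classified samples, n_correct / n_total."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {true.shape}")
    if predicted.size == 0:
        raise ValueError("empty input")
    return float(np.mean(predicted == true))


def r_squared(true: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative)."""
    true = np.asarray(true, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if true.shape != predicted.shape:
        raise ValueError(f"length mismatch: {true.shape} vs {predicted.shape}")
    if true.size < 2:
        raise ValueError("need at least two samples")
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance truth: R^2 undefined")
    ss_res = float(np.sum((true - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def confusion(predicted: np.ndarray, true: np.ndarray, n_classes: int) -> np.ndarray:
    """Count matrix [K x K]: entry (i, j) = true class i predicted as j."""
    predicted = np.asarray(predicted, dtype=int)
    true = np.asarray(true, dtype=int)
    if predicted.shape != true.shape:
        raise ValueError("length mismatch")
    for arr, name in ((predicted, "predicted"), (true, "true")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (true, predicted), 1)
    return mat


# ---------------------------------------------------------------------------
# paired nonparametric comparison
# ---------------------------------------------------------------------------

class DegenerateTestError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


@dataclass(frozen=True)
class ComparisonResult:
    model_a: str
    model_b: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    statistic: float  # W+ = sum of ranks of positive differences (a - b)
    p_value: float
    significant: bool
    n_zero_dropped: int


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p over all 2^m sign assignments.

    Average-tied ranks are doubled to integers; the null distribution of the
    doubled positive-rank sum is built by convolving (1 + x^(2r)) factors,
    which enumerates every sign assignment exactly.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    max_sum = int(doubled.sum())
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: max_sum + 1 - r].copy()
    total = counts.sum()  # 2^m
    w2 = int(round(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def paired_nonparametric_test(
    values_a, values_b, model_a: str = "a", model_b: str = "b",
    alpha: float = 0.05, exact_max_n: int = 25,
) -> ComparisonResult:
    """Wilcoxon signed-rank test on subject-paired scores (two-sided).

    Zero differences are dropped (count recorded); absolute differences are
    ranked with average ties. The null distribution is exact for up to
    ``exact_max_n`` nonzero pairs, otherwise a tie-corrected normal
    approximation is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired value vectors must be 1-D and equal length")
    d = a - b
    nonzero = d != 0
    n_dropped = int((~nonzero).sum())
    d = d[nonzero]
    if d.size == 0:
        raise DegenerateTestError(
            "all paired differences are zero; the two models are identical "
            "on every subject"
        )
    if n_dropped:
        logger.info("signed-rank test dropped %d zero difference(s)", n_dropped)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    m = d.size
    if m <= exact_max_n:
        p = _exact_signed_rank_p(w_plus, ranks)
    else:
        mu = m * (m + 1) / 4.0
        tie_term = float(np.sum(ranks**2))  # sum r_i^2 absorbs average-tie correction
        sigma = math.sqrt(tie_term / 4.0)
        z = (w_plus - mu) / sigma
        p = min(1.0, 2.0 * (1.0 - _norm_cdf(abs(z))))
    return ComparisonResult(
        model_a=model_a,
        model_b=model_b,
        values_a=tuple(map(float, values_a)),
        values_b=tuple(map(float, values_b)),
        statistic=w_plus,
        p_value=float(p),
        significant=bool(p < alpha),
        n_zero_dropped=n_dropped,
    )


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

def loto_folds(
    trials: list[TrialRecording],
) -> list[tuple[list[TrialRecording], TrialRecording]]:
    """Leave-one-trial-out folds for one subject, ordered by trial id."""
    if len(trials) < 2:
        raise ValueError("need at least two trials per subject")
    ids = [t.trial_id for t in trials]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate trial ids: {sorted(ids)}")
    ordered = sorted(trials, key=lambda t: t.trial_id)
    return [
        ([t for t in ordered if t.trial_id != test.trial_id], test)
        for test in ordered
    ]


@dataclass
class FoldResult:
    test_trial_id: int
    accuracy: float
    r2: float
    confusion: np.ndarray
    n_test: int
    provenance: dict


@dataclass
class CVResult:
    subject_id: int
    folds: list[FoldResult]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))

    @property
    def mean_r2(self) -> float:
        return float(np.mean([f.r2 for f in self.folds]))

    @property
    def total_confusion(self) -> np.ndarray:
        return np.sum([f.confusion for f in self.folds], axis=0)


@dataclass(frozen=True)
class DualNetSpec:
    """Model specification for a dual-output deep model in the harness.

    arrangement_mode: "paper_fixture" | "pair_complete" | "identity";
    cnn_aug defaults to the published fixture (10 channels) and uses square
    windows of the arrangement length; cnn_noaug and gru use the identity
    arrangement with a window of 10 raw time steps.
    """

    architecture: str = "cnn_aug"
    arrangement_mode: str | None = None
    window_len: int | None = None
    concat_mode: str = "paper"
    n_classes: int = 5
    model_kwargs: tuple = ()  # extra DualModelConfig fields, as sorted items

    @property
    def name(self) -> str:
        return self.architecture

    def _arrangement(self, n_channels: int) -> Arrangement:
        mode = self.arrangement_mode
        if mode is None:
            mode = "paper_fixture" if self.architecture == "cnn_aug" else "identity"
        if mode == "identity":
            return Arrangement(tuple(range(1, n_channels + 1)), n_channels)
        return build_arrangement(n_channels, mode)

    def run_fold(
        self,
        train_trials: list[TrialRecording],
        test_trial: TrialRecording,
        seed: int,
    ) -> FoldResult:
        std = fit_standardizer(train_trials)
        arr = self._arrangement(test_trial.n_channels)
        if self.window_len is not None:
            w = self.window_len
        elif self.architecture == "cnn_aug":
            w = arr.length  # square movement images
        elif self.architecture == "cnn_noaug":
            w = arr.length  # identity arrangement: w = M = channel count
        else:
            w = 10  # GRU timestep length
        train_ds = make_image_dataset(train_trials, arr, w, std, self.concat_mode)
        test_ds = make_image_dataset([test_trial], arr, w, std, "per_trial")
        kwargs = dict(self.model_kwargs)
        config = DualModelConfig(
            architecture=self.architecture,
            input_side=w,
            n_input_channels=arr.length,
            n_classes=self.n_classes,
            seed=seed,
            **kwargs,
        )
        net = build_model(config)
        trained = train(net, train_ds, config)
        _, pred_labels, pred_angles = predict(trained, test_ds.images)
        acc = accuracy(pred_labels, test_ds.labels)
        r2 = r_squared(test_ds.angles, pred_angles)
        cm = confusion(pred_labels, test_ds.labels, self.n_classes)
        provenance = {
            "std_fit_trials": sorted(t.trial_id for t in train_trials),
            "train_window_trials": sorted(
                set(train_ds.trial_start.tolist()) | set(train_ds.trial_end.tolist())
            ),
            "test_trial_id": test_trial.trial_id,
            "seed": seed,
            "model": self.architecture,
        }
        return FoldResult(
            test_trial_id=test_trial.trial_id,
            accuracy=acc,
            r2=r2,
            confusion=cm,
            n_test=len(test_ds),
            provenance=provenance,
        )


@dataclass(frozen=True)
class ShallowSpec:
    """Shallow benchmark pair in the harness: an SVC+SVR pair (family="svm")
    or a forest classifier+regressor pair (family="rf"), both operating on
    raw per-time-step standardized sensor vectors."""

    family: str = "svm"
    n_classes: int = 5
    config: ShallowConfig = ShallowConfig()

    @property
    def name(self) -> str:
        return self.family

    def run_fold(
        self,
        train_trials: list[TrialRecording],
        test_trial: TrialRecording,
        seed: int,
    ) -> FoldResult:
        if self.family not in ("svm", "rf"):
            raise ValueError(f"unknown shallow family {self.family!r}")
        std = fit_standardizer(train_trials)
        x_parts, lab_parts, ang_parts = [], [], []
        for t in sorted(train_trials, key=lambda t: t.trial_id):
            z, a = standardize_trial(t, std)
            x_parts.append(z)
            lab_parts.append(t.labels)
            ang_parts.append(a)
        x_train = np.concatenate(x_parts)
        y_train = np.concatenate(lab_parts)
        a_train = np.concatenate(ang_parts)
        x_test, a_test = standardize_trial(test_trial, std)
        cfg = replace(self.config, seed=seed)
        cls_kind, reg_kind = ("svc", "svr") if self.family == "svm" else ("rf_cls", "rf_reg")
        cls = fit_shallow(cls_kind, x_train, y_train, cfg)
        reg = fit_shallow(reg_kind, x_train, a_train, cfg)
        pred_labels = cls.predict(x_test)
        pred_angles = reg.predict(x_test)
        acc = accuracy(pred_labels, test_trial.labels)
        r2 = r_squared(a_test, pred_angles)
        cm = confusion(pred_labels, test_trial.labels, self.n_classes)
        provenance = {
            "std_fit_trials": sorted(t.trial_id for t in train_trials),
            "train_window_trials": sorted(t.trial_id for t in train_trials),
            "test_trial_id": test_trial.trial_id,
            "seed": seed,
            "model": self.family,
        }
        return FoldResult(
            test_trial_id=test_trial.trial_id,
            accuracy=acc,
            r2=r2,
            confusion=cm,
            n_test=len(test_trial.labels),
            provenance=provenance,
        )


def _fold_seed(root_seed: int, subject_id: int, fold_idx: int) -> int:
    ss = np.random.SeedSequence([root_seed, subject_id, fold_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    trials: list[TrialRecording],
    spec,
    root_seed: int = 0,
) -> tuple[list[CVResult], dict]:
    """Leave-one-trial-out evaluation of one model over the whole cohort.

    Returns per-subject CVResults and a pooled summary with the across-
    subject mean and standard deviation of accuracy and R^2 (the cohort
    headline numbers), plus fold bookkeeping.
    """
    by_subject: dict[int, list[TrialRecording]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    trial_counts = {len(v) for v in by_subject.values()}
    if len(trial_counts) != 1:
        raise ValueError("every subject must have the same trial count")
    results = []
    for subject_id in sorted(by_subject):
        folds = []
        for fold_idx, (train_trials, test_trial) in enumerate(
            loto_folds(by_subject[subject_id])
        ):
            seed = _fold_seed(root_seed, subject_id, fold_idx)
            fold = spec.run_fold(train_trials, test_trial, seed)
            logger.info(
                "subject %s fold %s (%s): accuracy=%.4f r2=%.4f",
                subject_id, fold_idx, spec.name, fold.accuracy, fold.r2,
            )
            folds.append(fold)
        results.append(CVResult(subject_id=subject_id, folds=folds))
    acc = np.array([r.mean_accuracy for r in results])
    r2 = np.array([r.mean_r2 for r in results])
    summary = {
        "model": spec.name,
        "n_subjects": len(results),
        "n_folds": sum(len(r.folds) for r in results),
        "mean_accuracy": float(acc.mean()),
        "sd_accuracy": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        "mean_r2": float(r2.mean()),
        "sd_r2": float(r2.std(ddof=1)) if len(r2) > 1 else 0.0,
        "root_seed": root_seed,
    }
    return results, summary


def results_table(results: list[CVResult]) -> pd.DataFrame:
    """Per-fold metric table (subject, test trial, accuracy, R^2, n_test)."""
    rows = [
        {
            "subject_id": r.subject_id,
            "test_trial_id": f.test_trial_id,
            "accuracy": f.accuracy,
            "r2": f.r2,
            "n_test": f.n_test,
        }
        for r in results
        for f in r.folds
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensor-count ablation
# ---------------------------------------------------------------------------

def restrict_channels(
    trials: list[TrialRecording], channels: tuple[int, ...]
) -> list[TrialRecording]:
    """Keep only the given 1-based channels, in the given order."""
    idx = np.asarray(channels) - 1
    return [
        TrialRecording(
            subject_id=t.subject_id,
            trial_id=t.trial_id,
            pressures=t.pressures[:, idx],
            labels=t.labels,
            angles=t.angles,
            sample_rate=t.sample_rate,
        )
        for t in trials
    ]


def _default_ablation_spec(k: int, base: DualNetSpec) -> DualNetSpec:
    mode = "paper_fixture" if k == 10 and base.arrangement_mode in (None, "paper_fixture") \
        else "pair_complete"
    if k == 1:
        # a single channel cannot form pairs; repeat it to the window length
        return replace(base, arrangement_mode="identity", window_len=None)
    return replace(base, arrangement_mode=mode, window_len=None)


def sensor_ablation(
    trials: list[TrialRecording],
    ranking: ImportanceRanking | None,
    k_range,
    spec: DualNetSpec | None = None,
    root_seed: int = 0,
    channel_override: dict[int, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Re-run the experiment with the top-k ranked sensors for each k.

    For each k the cohort is restricted to the k most important channels, a
    pair-complete arrangement is rebuilt for those channels (the published
    fixture only applies at k = 10), and the full leave-one-trial-out
    experiment is repeated. ``channel_override`` substitutes an explicit
    channel subset for a given k (used for forced-control comparisons).
    Returns one row per k: k, channels, mean/sd accuracy, mean/sd R^2.
    """
    if ranking is None and not channel_override:
        raise ValueError("need a ranking or an explicit channel override")
    if spec is None:
        spec = DualNetSpec(architecture="cnn_aug")
    rows = []
    for k in k_range:
        channels = (
            channel_override[k]
            if channel_override and k in channel_override
            else select_top_k(ranking, k)
        )
        sub = restrict_channels(trials, channels)
        k_spec = _default_ablation_spec(len(channels), spec)
        _, summary = run_experiment(sub, k_spec, root_seed=root_seed)
        rows.append(
            {
                "k": k,
                "channels": channels,
                "mean_accuracy": summary["mean_accuracy"],
                "sd_accuracy": summary["sd_accuracy"],
                "mean_r2": summary["mean_r2"],
                "sd_r2": summary["sd_r2"],
            }
        )
    return pd.DataFrame(rows)


def sensor_ablation_strict(
    trials: list[TrialRecording],
    k_range,
    spec: DualNetSpec | None = None,
    shallow_config: ShallowConfig | None = None,
    root_seed: int = 0,
) -> pd.DataFrame:
    """Leakage-safe ablation: channel importances are re-fitted inside each
    fold on that fold's training trials only, so the test trial never
    influences channel selection. Slower than :func:`sensor_ablation`, which
    follows the global-importance recipe."""
    from .shallow import compute_importance

    if spec is None:
        spec = DualNetSpec(architecture="cnn_aug")
    if shallow_config is None:
        shallow_config = ShallowConfig()
    by_subject: dict[int, list[TrialRecording]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    rows = []
    for k in k_range:
        accs, r2s = [], []
        for subject_id in sorted(by_subject):
            for fold_idx, (train_trials, test_trial) in enumerate(
                loto_folds(by_subject[subject_id])
            ):
                std = fit_standardizer(train_trials)
                feats, labs, angs = [], [], []
                for t in train_trials:
                    z, a = standardize_trial(t, std)
                    feats.append(z)
                    labs.append(t.labels)
                    angs.append(a)
                fold_ranking = compute_importance(
                    [(np.concatenate(feats), np.concatenate(labs),
                      np.concatenate(angs))],
                    shallow_config,
                )
                channels = select_top_k(fold_ranking, k)
                sub_train = restrict_channels(train_trials, channels)
                sub_test = restrict_channels([test_trial], channels)[0]
                k_spec = _default_ablation_spec(len(channels), spec)
                seed = _fold_seed(root_seed, subject_id, fold_idx)
                fold = k_spec.run_fold(sub_train, sub_test, seed)
                accs.append(fold.accuracy)
                r2s.append(fold.r2)
        rows.append(
            {
                "k": k,
                "mean_accuracy": float(np.mean(accs)),
                "mean_r2": float(np.mean(r2s)),
            }
        )
    return pd.DataFrame(rows)
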