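"""Cross-validated evaluation and group comparison.

Classification quality is summarized from pooled confusion counts per
cross-validation fold, with the impaired group as the positive class:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * precision * recall / (precision + recall)

all reported as percentages.  Folds are either random over samples (the
default, which lets trials of one subject span folds) or grouped by
subject (recommended: no subject appears in both a training and a test
fold).  ``compare_group_timecourses`` reproduces the classic group-level
analysis: subject-mean dHbO over ROI channels, group mean +/- SD curves,
and a two-sample t-test on the task-window means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .cnn import CNNArchitecture, SmallCNN, TrainConfig

__all__ = [
    "ConfusionCounts",
    "FoldPlan",
    "kfold_split",
    "compute_metrics",
    "cross_validate",
    "CVResults",
    "metrics_table",
    "compare_group_timecourses",
]

METRIC_NAMES = ("accuracy", "recall", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with the impaired group as positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive: int = 1) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == positive) & (y_pred == positive))),
            tn=int(np.sum((y_true != positive) & (y_pred != positive))),
            fp=int(np.sum((y_true != positive) & (y_pred == positive))),
            fn=int(np.sum((y_true == positive) & (y_pred != positive))),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The four confusion-based metrics in percent.

    Recall is undefined (NaN) when TP + FN = 0, precision when
    TP + FP = 0, and F1 when either is undefined or precision + recall
    is zero; NaN entries are excluded from averaging downstream.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    accuracy = 100.0 * (c.tp + c.tn) / c.total
    recall = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else float("nan")
    precision = 100.0 * c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else float("nan")
    if np.isnan(recall) or np.isnan(precision) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "recall": recall, "precision": precision, "f1": f1}


@dataclass(frozen=True)
class FoldPlan:
    """K disjoint test partitions covering every sample exactly once."""

    test_folds: tuple[np.ndarray, ...]
    mode: str
    seed: int

    @property
    def k(self) -> int:
        return len(self.test_folds)

    def train_indices(self, fold: int, n: int) -> np.ndarray:
        mask = np.ones(n, dtype=bool)
        mask[self.test_folds[fold]] = False
        return np.flatnonzero(mask)


def kfold_split(
    n_samples: int,
    k: int = 5,
    mode: str = "sample",
    seed: int = 0,
    subjects: Sequence | None = None,
) -> FoldPlan:
    """Random k-fold partition of ``n_samples`` sample indices.

    ``mode="sample"`` splits samples directly (fold sizes differ by at
    most one); ``mode="subject"`` requires ``subjects`` (one id per
    sample) and keeps all samples of a subject in the same fold.
    """
    if mode == "sample":
        if n_samples < k:
            raise ValueError("fewer samples than folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = tuple(test for _, test in splitter.split(np.arange(n_samples)))
    elif mode == "subject":
        if subjects is None:
            raise ValueError("subject mode requires per-sample subject ids")
        subjects = np.asarray(subjects)
        unique = np.unique(subjects)
        if unique.size < k:
            raise ValueError("fewer subjects than folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = tuple(
            np.flatnonzero(np.isin(subjects, unique[test]))
            for _, test in splitter.split(unique)
        )
    else:
        raise ValueError(f"unknown CV mode {mode!r}")
    return FoldPlan(test_folds=folds, mode=mode, seed=seed)


@dataclass
class CVResults:
    """Per-fold confusion counts and metrics with summary helpers."""

    fold_counts: list[ConfusionCounts]
    fold_metrics: pd.DataFrame
    skipped_folds: list[int] = field(default_factory=list)

    def mean(self) -> pd.Series:
        """NaN-excluding mean of each metric across folds (percent)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return self.fold_metrics[list(METRIC_NAMES)].mean(skipna=True)

    def std(self) -> pd.Series:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return self.fold_metrics[list(METRIC_NAMES)].std(skipna=True)

    def pooled(self) -> dict[str, float]:
        """Metrics of the summed confusion counts over all folds."""
        total = ConfusionCounts(0, 0, 0, 0)
        for c in self.fold_counts:
            total = total + c
        return compute_metrics(total)

    def summary(self) -> pd.DataFrame:
        frame = self.fold_metrics.copy()
        frame.loc["mean"] = self.mean()
        frame.loc["std"] = self.std()
        return frame


def _fold_scale(train_images: np.ndarray) -> tuple[float, float]:
    lo = float(train_images.min())
    hi = float(train_images.max())
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def cross_validate(
    images: np.ndarray,
    labels: np.ndarray,
    arch: CNNArchitecture = CNNArchitecture(),
    cfg: TrainConfig = TrainConfig(),
    plan: FoldPlan | None = None,
    seed: int = 0,
) -> CVResults:
    """K-fold cross-validation of the CNN on raw-valued feature maps.

    Per fold, the affine value scale is computed from the *training*
    images only and applied (with clipping to [0, 1]) to both partitions
    before training, so no test-set statistics leak into the inputs.  A
    fold whose training partition contains a single class is skipped with
    a warning and excluded from the averages.
    """
    images = np.asarray(images)
    labels = np.asarray(labels, dtype=int)
    n = images.shape[0]
    if plan is None:
        plan = kfold_split(n, seed=seed)
    rows = []
    counts = []
    skipped = []
    for fold, test_idx in enumerate(plan.test_folds):
        train_idx = plan.train_indices(fold, n)
        if np.unique(labels[train_idx]).size < 2:
            warnings.warn(f"fold {fold}: single-class training partition, skipped")
            skipped.append(fold)
            continue
        lo, hi = _fold_scale(images[train_idx])
        train = np.clip((images[train_idx] - lo) / (hi - lo), 0.0, 1.0)
        test = np.clip((images[test_idx] - lo) / (hi - lo), 0.0, 1.0)
        model = SmallCNN(arch, seed=_fold_seed(seed, fold))
        model.fit(train, labels[train_idx],
                  cfg=TrainConfig(**{**cfg.__dict__, "seed": _fold_seed(seed, fold)}))
        pred = model.predict(test)
        c = ConfusionCounts.from_predictions(labels[test_idx], pred)
        counts.append(c)
        rows.append({"fold": fold, **compute_metrics(c)})
    if not rows:
        raise ValueError("every fold was skipped; no class balance in the data")
    frame = pd.DataFrame(rows).set_index("fold")
    return CVResults(fold_counts=counts, fold_metrics=frame, skipped_folds=skipped)


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 1000 + fold) % (2**31 - 1)


def metrics_table(results_by_feature: Mapping[str, CVResults]) -> pd.DataFrame:
    """Report table: one row per feature type (fold means), plus Average
    and STD rows across feature types, each metric in percent."""
    rows = {name: res.mean() for name, res in results_by_feature.items()}
    frame = pd.DataFrame(rows).T
    frame.loc["Average"] = frame.mean(skipna=True)
    frame.loc["STD"] = frame.drop(index="Average").std(skipna=True)
    return frame


def compare_group_timecourses(
    epochs: Mapping[tuple[str, str, int], np.ndarray],
    groups: Mapping[str, str],
    fs: float,
    task: str,
    roi_channels: Mapping[tuple[str, str, int], np.ndarray] | None = None,
    window_s: tuple[float, float] = (5.0, 65.0),
    equal_var: bool = False,
) -> dict:
    """Group-level dHbO comparison for one task.

    Each subject contributes the mean dHbO curve over their ROI channels
    (all channels when a trial has no ROI set or none is supplied),
    averaged over trials.  Returns the group mean and SD curves and a
    two-sample t-test (Welch by default, pooled with ``equal_var=True``)
    comparing the groups' mean response in ``window_s``.
    """
    per_subject: dict[str, list[np.ndarray]] = {}
    for (subject, t, trial), epoch in epochs.items():
        if t != task:
            continue
        chans = None
        if roi_channels is not None:
            chans = np.asarray(roi_channels.get((subject, t, trial), []), dtype=int)
        if chans is None or chans.size == 0:
            curve = epoch.mean(axis=0)
        else:
            curve = epoch[chans].mean(axis=0)
        per_subject.setdefault(subject, []).append(curve)

    curves = {s: np.mean(v, axis=0) for s, v in per_subject.items()}
    impaired = [s for s in curves if groups[s] == "impaired"]
    control = [s for s in curves if groups[s] == "control"]
    if len(impaired) < 2 or len(control) < 2:
        raise ValueError("need at least 2 subjects per group")

    i0 = int(round(window_s[0] * fs))
    i1 = int(round(window_s[1] * fs))
    imp = np.stack([curves[s] for s in impaired])
    con = np.stack([curves[s] for s in control])
    imp_means = imp[:, i0 : i1 + 1].mean(axis=1)
    con_means = con[:, i0 : i1 + 1].mean(axis=1)
    t_stat, p_value = stats.ttest_ind(imp_means, con_means, equal_var=equal_var)
    return {
        "task": task,
        "time_s": np.arange(imp.shape[1]) / fs,
        "impaired_mean": imp.mean(axis=0),
        "impaired_sd": imp.std(axis=0, ddof=1),
        "control_mean": con.mean(axis=0),
        "control_sd": con.std(axis=0, ddof=1),
        "t": float(t_stat),
        "p": float(p_value),
        "window_s": window_s,
        "n_impaired": len(impaired),
        "n_control": len(control),
    }


def plot_group_timecourses(result: dict, ax=None):
    """Mean +/- SD band plot of the two groups' dHbO time courses."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = result["time_s"]
    for key, color in (("impaired", "tab:red"), ("control", "tab:blue")):
        mean = result[f"{key}_mean"]
        sd = result[f"{key}_sd"]
        ax.plot(t, mean, color=color, label=key)
        ax.fill_between(t, mean - sd, mean + sd, color=color, alpha=0.2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("dHbO (uM)")
    ax.set_title(f"{result['task']}: group mean dHbO (p = {result['p']:.2g})")
    ax.legend()
    return ax
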