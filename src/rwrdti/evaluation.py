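"""ROC/AUC evaluation, cross-validation and paired comparisons.

Because training negatives are randomly sampled, every headline number is
computed once per replicate negative set and reported as mean +/- sd over
replicates; two weighting schemes are compared with a paired t-test across
the replicate AUCs (paired by negative-set index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .dti_model import CubicKNN, PairDataset

__all__ = [
    "EvalReport",
    "roc_auc",
    "cross_validate",
    "evaluate_on_test",
    "paired_t_test",
    "sweep_restart_c",
    "plot_roc",
]


@dataclass
class EvalReport:
    """Per-replicate AUCs with their mean and standard deviation.

    ``roc_points`` holds one (fpr, tpr) curve per replicate (or per fold),
    each starting at (0, 0) and ending at (1, 1).
    """

    auc_per_negative_set: list[float]
    roc_points: list[np.ndarray] = field(default_factory=list)
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_negative_set))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.auc_per_negative_set, ddof=1)) if len(
            self.auc_per_negative_set
        ) > 1 else 0.0

    def __str__(self) -> str:
        return (
            f"AUC {self.mean_auc:.3f}(+/-{self.sd_auc:.3f}) over "
            f"{len(self.auc_per_negative_set)} replicate(s)"
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "auc_per_negative_set": list(map(float, self.auc_per_negative_set)),
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "config": self.config,
        }


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, np.ndarray]:
    """Trapezoidal ROC AUC (equivalent to the Mann-Whitney statistic,
    counting ties as half-concordant) plus the (fpr, tpr) curve points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(
            f"both classes must be present to compute an AUC (got {classes})"
        )
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(_trapezoid_auc(fpr, tpr)), np.column_stack([fpr, tpr])


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    rng_seed: int = 0,
    k: int = 10,
) -> EvalReport:
    """Stratified k-fold cross-validation of the cubic kNN; one AUC per
    fold. Deterministic given ``rng_seed``."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    aucs, curves = [], []
    for train_idx, test_idx in skf.split(X, y):
        if np.unique(y[test_idx]).size < 2 or np.unique(y[train_idx]).size < 2:
            raise ValueError(
                "a fold lacks one of the classes; use fewer folds or more data"
            )
        model = CubicKNN(k=min(k, len(train_idx))).fit(X[train_idx], y[train_idx])
        a, pts = roc_auc(model.score_samples(X[test_idx]), y[test_idx])
        aucs.append(a)
        curves.append(pts)
    return EvalReport(aucs, curves, {"n_folds": n_folds, "rng_seed": rng_seed, "k": k})


def evaluate_on_test(
    dataset: PairDataset,
    X_test: np.ndarray,
    y_test: np.ndarray,
    k: int = 10,
) -> EvalReport:
    """Train one cubic kNN per replicate negative set and score a fixed
    test set; one AUC per replicate."""
    if dataset.n_negative_sets == 0:
        raise ValueError("dataset carries no negative sets")
    aucs, curves = [], []
    for j in range(dataset.n_negative_sets):
        Xr, yr = dataset.replicate(j)
        model = CubicKNN(k=k).fit(Xr, yr)
        a, pts = roc_auc(model.score_samples(X_test), y_test)
        aucs.append(a)
        curves.append(pts)
    return EvalReport(aucs, curves, {"k": k, "n_sets": dataset.n_negative_sets})


def paired_t_test(
    auc_a: Sequence[float], auc_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided paired t-test of per-replicate AUCs (paired by
    negative-set index). Returns (t, p)."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length AUC lists of length >= 2")
    diff = a - b
    spread = float(np.abs(diff).max())
    if np.std(diff, ddof=1) <= 1e-12 * max(1.0, spread):
        if spread == 0:  # identical lists: no difference at all
            return 0.0, 1.0
        raise ValueError("zero variance of paired differences; t is undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def sweep_restart_c(model, c_grid: Sequence[float], test_pairs=None, **fit_kw):
    """Re-run weighting + training + evaluation across a grid of restart
    probabilities; returns a table of (c, train_auc, test_auc).

    Thin convenience wrapper over
    :meth:`rwrdti.model.DTIPropagationModel.sweep_restart_c`.
    """
    return model.sweep_restart_c(c_grid, test_pairs=test_pairs, **fit_kw)


def plot_roc(report: EvalReport, path: str, title: str = "ROC") -> None:
    """Save the replicate ROC curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for pts in report.roc_points:
        ax.plot(pts[:, 0], pts[:, 1], alpha=0.4, lw=1)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"{title} — {report}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
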