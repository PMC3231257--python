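"""Evaluation protocol: 1-NN classification under subject-grouped
10-fold cross-validation with an embedded-dimension sweep and an
exhaustive alpha search for the supervised embedding.

Folds partition *subjects*, not images, so no individual appears in both
the training and the test side of a fold.  For every fold and method the
embedding is fitted on the training folds only, the held-out fold is
projected with the method's out-of-sample extension, and a nearest
neighbor classifier (Euclidean metric, ties to the smallest training
index) predicts its labels.  Accuracies are reported as mean +/- sd
across folds per (method, dimension, alpha) cell.

Two alpha-selection protocols are provided for KDIsomap:

* ``alpha_mode="sweep"`` reports the whole (dimension, alpha) grid and
  the best cell by outer test accuracy — an optimistic, exploratory
  reading of an exhaustive search;
* ``alpha_mode="inner"`` picks alpha per dimension by an inner
  subject-grouped cross-validation inside the training folds, so the
  test fold never influences the choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .baselines import (
    kernel_transform,
    klda_fit,
    kpca_fit,
    lda_fit,
    linear_transform,
    pca_fit,
)
from .isomap import kdisomap_fit, kisomap_fit, transform as isomap_transform
from .kernel_distance import DiscriminantParams, KernelParams

__all__ = [
    "METHODS",
    "CvPlan",
    "SweepGrid",
    "ExperimentResult",
    "nn_classify",
    "subject_kfold",
    "confusion_matrix",
    "run_experiment",
    "default_dimension_grid",
]

logger = logging.getLogger(__name__)

METHODS = ("pca", "lda", "kpca", "klda", "kisomap", "kdisomap")


def nn_classify(train_coords, train_labels, test_coords) -> np.ndarray:
    """Nearest-neighbor prediction under the Euclidean metric.

    Each test point receives the label of its closest training point;
    distance ties resolve to the smallest training index.
    """
    train_coords = np.atleast_2d(np.asarray(train_coords, dtype=np.float64))
    test_coords = np.atleast_2d(np.asarray(test_coords, dtype=np.float64))
    train_labels = np.asarray(train_labels)
    if train_coords.shape[0] == 0:
        raise ValueError("empty training set")
    if train_coords.shape[1] != test_coords.shape[1]:
        raise ValueError(
            f"coordinate dimension mismatch: {train_coords.shape[1]} vs "
            f"{test_coords.shape[1]}"
        )
    dist = cdist(test_coords, train_coords)
    return train_labels[np.argmin(dist, axis=1)]  # argmin takes the first minimum


@dataclass(frozen=True)
class CvPlan:
    """Subject-grouped fold assignment: ``fold_of[subject] -> fold index``."""

    fold_of: dict
    n_folds: int
    seed: int

    def fold_indices(self, subjects) -> list[np.ndarray]:
        """Per-fold sample index arrays for a subject vector."""
        subjects = np.asarray(subjects)
        folds = np.array([self.fold_of[s] for s in subjects])
        return [np.flatnonzero(folds == f) for f in range(self.n_folds)]


def subject_kfold(subjects, n_folds: int = 10, seed: int = 0) -> CvPlan:
    """Randomly partition subjects into folds of near-equal size.

    Every sample of a subject shares that subject's fold; fold sizes
    differ by at most one subject.  Deterministic under ``seed``.
    """
    uniq = np.unique(np.asarray(subjects))
    if len(uniq) < n_folds:
        raise ValueError(
            f"need at least {n_folds} distinct subjects, got {len(uniq)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[uniq[idx].item() if hasattr(uniq[idx], "item") else uniq[idx]] = (
            pos % n_folds
        )
    return CvPlan(assignment, n_folds, seed)


def confusion_matrix(true, predicted, classes) -> np.ndarray:
    """Row-normalized confusion matrix in percent.

    Rows follow the given class order (true class), columns the same
    order (predicted class); each non-empty row sums to 100.  Rows of
    classes absent from ``true`` are NaN and logged.
    """
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.shape != predicted.shape:
        raise ValueError("true and predicted label sequences differ in length")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    for lab in np.unique(np.concatenate([true, predicted])):
        key = lab.item() if hasattr(lab, "item") else lab
        if key not in index:
            raise ValueError(f"label {lab!r} not in the class list")
    counts = np.zeros((len(classes), len(classes)))
    for t, p in zip(true, predicted):
        counts[index[t.item() if hasattr(t, "item") else t],
               index[p.item() if hasattr(p, "item") else p]] += 1
    rows = counts.sum(axis=1)
    out = np.full_like(counts, np.nan)
    ok = rows > 0
    out[ok] = 100.0 * counts[ok] / rows[ok, None]
    if not ok.all():
        logger.warning("classes with no true samples: %s",
                       [classes[i] for i in np.flatnonzero(~ok)])
    return out


def default_dimension_grid(max_dim: int = 100) -> list[int]:
    """[2, 100] in steps of 5 merged with [2, 10] in steps of 1."""
    dims = sorted(set(range(2, max_dim + 1, 5)) | {max_dim}
                  | set(range(2, min(10, max_dim) + 1)))
    return [d for d in dims if d >= 2]


DEFAULT_ALPHAS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass
class SweepGrid:
    """Dimension and alpha grids for the sweep.

    LDA-type methods are automatically capped at c - 1 dimensions.
    """

    dimensions: tuple = tuple(default_dimension_grid())
    alphas: tuple = DEFAULT_ALPHAS

    def dims_for(self, method: str, n_classes: int, n_train: int) -> list[int]:
        if method in ("lda", "klda"):
            cap = n_classes - 1
        elif method == "pca":
            cap = n_train
        else:
            cap = n_train
        dims = sorted({min(d, cap) for d in self.dimensions if d >= 1})
        return dims


@dataclass
class ExperimentResult:
    """Sweep results: per-cell accuracy table and best-cell summaries."""

    table: pd.DataFrame  # method, dimension, alpha, mean, sd, n_folds
    best: pd.DataFrame  # per-method best cell
    predictions: dict  # method -> (true, predicted) at the best cell
    confusions: dict  # method -> row-normalized % confusion matrix
    classes: list
    fold_eigenvalues: dict = field(default_factory=dict)  # sentinel support
    seed: int = 0

    def best_accuracy(self, method: str) -> float:
        row = self.best[self.best.method == method]
        if row.empty:
            raise KeyError(f"no results for method {method!r}")
        return float(row["mean"].iloc[0])


def _fit_and_project(method, Xtr, ytr, Xte, d_max, k, kp, alpha):
    """Fit one embedding at its maximal dimension; return train/test coords
    (N x d_max, M x d_max) ordered so that the leading columns are the
    top-d embedding for every smaller d."""
    if method == "pca":
        m = pca_fit(Xtr, d_max)
        return linear_transform(m, Xtr), linear_transform(m, Xte), None
    if method == "lda":
        m = lda_fit(Xtr, ytr, d_max)
        return linear_transform(m, Xtr), linear_transform(m, Xte), None
    if method == "kpca":
        m = kpca_fit(Xtr, d_max, kp)
        return kernel_transform(m, Xtr), kernel_transform(m, Xte), None
    if method == "klda":
        m = klda_fit(Xtr, ytr, d_max, kp)
        return kernel_transform(m, Xtr), kernel_transform(m, Xte), None
    if method == "kisomap":
        m = kisomap_fit(Xtr, k=k, d=d_max, auto_connect=True)
        return m.Y.T, isomap_transform(m, Xte).T, m.eigenvalues
    if method == "kdisomap":
        m = kdisomap_fit(
            Xtr,
            ytr,
            k=k,
            d=d_max,
            kernel_params=kp,
            discriminant_params=DiscriminantParams(alpha=alpha),
            auto_connect=True,
        )
        return m.Y.T, isomap_transform(m, Xte).T, m.eigenvalues
    raise ValueError(f"unknown method {method!r}")


def _select_alpha_inner(
    Xtr, ytr, str_, d, k, kp, alphas, n_inner, seed
) -> float:
    """Pick alpha by inner subject-grouped CV inside the training folds."""
    uniq = np.unique(str_)
    n_inner = min(n_inner, len(uniq))
    plan = subject_kfold(str_, n_folds=n_inner, seed=seed)
    folds = plan.fold_indices(str_)
    scores = np.zeros(len(alphas))
    for fi, te_idx in enumerate(folds):
        tr_idx = np.setdiff1d(np.arange(len(ytr)), te_idx)
        for ai, a in enumerate(alphas):
            try:
                Ztr, Zte, _ = _fit_and_project(
                    "kdisomap", Xtr[tr_idx], ytr[tr_idx], Xtr[te_idx], d, k, kp, a
                )
            except Exception as exc:  # noqa: BLE001 - a failed cell scores 0
                logger.warning("inner fold %d alpha=%.2f failed: %s", fi, a, exc)
                continue
            pred = nn_classify(Ztr[:, :d], ytr[tr_idx], Zte[:, :d])
            scores[ai] += float(np.mean(pred == ytr[te_idx]))
    return float(alphas[int(np.argmax(scores))])


def run_experiment(
    X,
    labels,
    subjects,
    methods=METHODS,
    grid: SweepGrid | None = None,
    cv: CvPlan | None = None,
    n_folds: int = 10,
    seed: int = 0,
    k: int = 10,
    kernel_params: KernelParams = KernelParams(),
    alpha_mode: str = "sweep",
    n_inner: int = 5,
) -> ExperimentResult:
    """Run the full sweep-and-evaluate protocol on a feature dataset.

    Fits every method on the training side of each fold, projects the
    held-out fold out-of-sample, classifies by 1-NN and aggregates
    accuracy (in percent) across folds for every (method, dimension,
    alpha) cell.  Cells whose embedding fails (e.g. a disconnected
    neighborhood graph) are recorded as invalid rather than aborting.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    if grid is None:
        grid = SweepGrid()
    if cv is None:
        cv = subject_kfold(subjects, n_folds=n_folds, seed=seed)
    if alpha_mode not in ("sweep", "inner"):
        raise ValueError(f"alpha_mode must be 'sweep' or 'inner', got {alpha_mode!r}")
    classes = [c.item() if hasattr(c, "item") else c for c in np.unique(labels)]
    folds = cv.fold_indices(subjects)
    n = X.shape[0]

    records = []
    fold_preds = {}  # (method, d, alpha) -> list of (true, pred) per fold
    fold_eigs = {}
    for fi, te_idx in enumerate(folds):
        tr_idx = np.setdiff1d(np.arange(n), te_idx)
        Xtr, ytr, Xte, yte = X[tr_idx], labels[tr_idx], X[te_idx], labels[te_idx]
        str_ = subjects[tr_idx]
        for method in methods:
            dims = grid.dims_for(method, len(classes), len(tr_idx))
            d_max = max(dims)
            if method == "kdisomap":
                if alpha_mode == "inner":
                    alphas_run = None  # chosen per dimension below
                else:
                    alphas_run = grid.alphas
            else:
                alphas_run = (None,)

            if method == "kdisomap" and alpha_mode == "inner":
                for d in dims:
                    a = _select_alpha_inner(
                        Xtr, ytr, str_, d, k, kernel_params, grid.alphas,
                        n_inner, seed + 1000 + fi,
                    )
                    try:
                        Ztr, Zte, eig = _fit_and_project(
                            method, Xtr, ytr, Xte, d, k, kernel_params, a
                        )
                    except Exception as exc:  # noqa: BLE001
                        logger.warning(
                            "fold %d %s d=%d failed: %s", fi, method, d, exc
                        )
                        continue
                    pred = nn_classify(Ztr[:, :d], ytr, Zte[:, :d])
                    acc = 100.0 * float(np.mean(pred == yte))
                    records.append((fi, method, d, a, acc))
                    fold_preds.setdefault((method, d, a), []).append((yte, pred))
                continue

            for a in alphas_run:
                try:
                    Ztr, Zte, eig = _fit_and_project(
                        method, Xtr, ytr, Xte, d_max, k, kernel_params, a
                    )
                except Exception as exc:  # noqa: BLE001
                    logger.warning("fold %d %s failed: %s", fi, method, exc)
                    continue
                if eig is not None:
                    fold_eigs[(method, fi, a)] = eig.copy()
                for d in dims:
                    pred = nn_classify(Ztr[:, :d], ytr, Zte[:, :d])
                    acc = 100.0 * float(np.mean(pred == yte))
                    records.append((fi, method, d, a, acc))
                    fold_preds.setdefault((method, d, a), []).append((yte, pred))

    raw = pd.DataFrame(records, columns=["fold", "method", "dimension", "alpha", "acc"])
    if raw.empty:
        raise RuntimeError("every cell of the sweep failed")
    table = (
        raw.groupby(["method", "dimension", "alpha"], dropna=False)["acc"]
        .agg(mean="mean", sd="std", n_folds="count")
        .reset_index()
        .sort_values(["method", "dimension", "alpha"])
        .reset_index(drop=True)
    )
    table["sd"] = table["sd"].fillna(0.0)

    best_rows = []
    predictions = {}
    confusions = {}
    for method in methods:
        sub = table[table.method == method]
        if sub.empty:
            continue
        row = sub.loc[sub["mean"].idxmax()]
        best_rows.append(row)
        key = (method, int(row.dimension),
               None if pd.isna(row.alpha) else float(row.alpha))
        pairs = fold_preds.get((method, key[1], key[2]), [])
        true = np.concatenate([t for t, _ in pairs]) if pairs else np.array([])
        pred = np.concatenate([p for _, p in pairs]) if pairs else np.array([])
        predictions[method] = (true, pred)
        if true.size:
            confusions[method] = confusion_matrix(true, pred, classes)
    best = pd.DataFrame(best_rows).reset_index(drop=True)

    return ExperimentResult(
        table=table,
        best=best,
        predictions=predictions,
        confusions=confusions,
        classes=classes,
        fold_eigenvalues=fold_eigs,
        seed=seed,
    )


def plot_accuracy_curves(result: ExperimentResult, path=None):
    """Accuracy-vs-dimension curves, one line per method (best alpha)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for method in result.table.method.unique():
        sub = result.table[result.table.method == method]
        curve = sub.groupby("dimension")["mean"].max()
        ax.plot(curve.index, curve.values, marker="o", label=method)
    ax.set_xlabel("embedded dimension")
    ax.set_ylabel("mean recognition accuracy (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
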