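"""Feature selection, fusion and SVM classification with leave-one-out CV.

The protocol: for each left-out subject, two-sample t-tests on the training
side select, per metric channel, the regional features differing between
cases and controls at p < 0.05 (uncorrected); the selected features are
concatenated in a fixed metric order (ReHo, ALFF, RFCS, GM, WM, CSF),
z-scored with training-fold parameters, and fed to a C-SVC with a hyperbolic
tangent (sigmoid) kernel whose C and G are chosen by an exhaustive grid
search over 2^-10 ... 2^10 scored by inner leave-one-out accuracy on the
training fold. The classifier's signed decision value for the held-out
subject is its abnormality index-score: positive scores are classified as
patients. Accuracy, sensitivity, specificity, the ROC curve/AUC over the
index-scores, per-fold selection counts and a selection-frequency report
summarise the run.

The fully nested protocol (feature selection, scaling and the grid search
all recomputed inside every fold) is the default; a "global" compatibility
mode picks a single (C, G) from a grid search on the whole cohort, which is
optimistically biased and provided only for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from ._svm import PrecomputedSVM, fit_predict_label, sigmoid_kernel
from .fmri_metrics import METRIC_TAGS

__all__ = [
    "FeatureBundle",
    "SelectionResult",
    "SvmGrid",
    "FoldResult",
    "EvaluationSummary",
    "two_sample_t",
    "select_features",
    "fuse",
    "standardize",
    "grid_search_svm",
    "loocv",
    "confusion_metrics",
    "roc_auc",
    "selection_frequency",
    "bundles_to_frame",
    "frame_to_bundles",
]

#: fixed concatenation order of the metric channels
METRIC_ORDER = METRIC_TAGS  # ("ReHo", "ALFF", "RFCS", "GM", "WM", "CSF")

GROUPS = ("case", "control")


@dataclass
class FeatureBundle:
    """Per-subject regional feature vectors, one per metric channel."""

    subject_id: str
    group: str
    features: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        self.features = {k: np.asarray(v, dtype=float)
                         for k, v in self.features.items()}


@dataclass
class SelectionResult:
    """Per metric, the (region index, statistic, p) triples retained."""

    per_metric: dict[str, list[tuple[int, float, float]]]
    alpha: float

    def indices(self, metric: str) -> list[int]:
        return [i for i, _, _ in self.per_metric.get(metric, [])]

    @property
    def counts(self) -> dict[str, int]:
        return {m: len(v) for m, v in self.per_metric.items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SvmGrid:
    """Hyper-parameter grid: C and G over powers of two, sigmoid kernel."""

    c_exponents: tuple[int, ...] = tuple(range(-10, 11))
    g_exponents: tuple[int, ...] = tuple(range(-10, 11))
    coef0: float = 0.0

    @property
    def c_values(self) -> np.ndarray:
        return 2.0 ** np.asarray(self.c_exponents, dtype=float)

    @property
    def g_values(self) -> np.ndarray:
        return 2.0 ** np.asarray(self.g_exponents, dtype=float)

    @property
    def n_pairs(self) -> int:
        return len(self.c_exponents) * len(self.g_exponents)


@dataclass
class FoldResult:
    held_out: str
    selection: SelectionResult
    C: float
    G: float
    inner_accuracy: float
    index_score: float
    predicted: str
    truth: str


@dataclass
class EvaluationSummary:
    accuracy: float          # percent
    sensitivity: float       # percent
    specificity: float       # percent
    auc: float
    n_folds: int
    scores: dict[str, float]
    truths: dict[str, str]
    fold_counts: pd.DataFrame = field(repr=False)
    mode: str = "nested"


# ---------------------------------------------------------------------------
# Feature selection


def two_sample_t(values_case: np.ndarray, values_control: np.ndarray,
                 equal_var: bool = True,
                 method: str = "t") -> tuple[float, float]:
    """Two-sided two-sample test; positive statistic = higher in cases.

    ``method='t'`` is Student's t with pooled variance (``equal_var=False``
    gives Welch); ``method='ranksum'`` is the Wilcoxon rank-sum alternative.
    Zero combined variance yields (0, 1).
    """
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    if method == "t":
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    elif method == "ranksum":
        res = stats.ranksums(a, b)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        return 0.0, 1.0
    return t, p


def _column_tests(case_mat: np.ndarray, ctrl_mat: np.ndarray,
                  method: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised column-wise two-sample tests; zero-variance columns -> (0, 1)."""
    degenerate = np.var(np.vstack([case_mat, ctrl_mat]), axis=0) == 0
    if method == "t":
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(case_mat, ctrl_mat, axis=0, equal_var=True)
        t_arr = np.asarray(res.statistic, dtype=float)
        p_arr = np.asarray(res.pvalue, dtype=float)
    elif method == "ranksum":
        t_arr = np.empty(case_mat.shape[1])
        p_arr = np.empty(case_mat.shape[1])
        for j in range(case_mat.shape[1]):
            t_arr[j], p_arr[j] = two_sample_t(case_mat[:, j], ctrl_mat[:, j],
                                              method="ranksum")
    else:
        raise ValueError(f"unknown selection method {method!r}")
    bad = degenerate | ~np.isfinite(t_arr)
    t_arr[bad] = 0.0
    p_arr[bad] = 1.0
    return t_arr, p_arr


def select_features(train: list[FeatureBundle], alpha: float = 0.05,
                    method: str = "t",
                    metrics: tuple[str, ...] | None = None,
                    correction: str | None = None) -> SelectionResult:
    """Retain, per metric, the regions with group differences at p < alpha.

    No multiple-testing correction is applied by default (deliberately
    uncorrected); ``correction='bonferroni'`` is available. If every metric
    retains zero features, the single smallest-p feature overall is kept so
    a fold can proceed (logged).
    """
    metrics = _resolve_metrics(train, metrics)
    case_idx = [i for i, b in enumerate(train) if b.group == "case"]
    ctrl_idx = [i for i, b in enumerate(train) if b.group == "control"]
    if not case_idx or not ctrl_idx:
        raise ValueError("training set must contain both groups")
    per_metric: dict[str, list[tuple[int, float, float]]] = {}
    best: tuple[float, str, int, float] | None = None  # (p, metric, idx, t)
    for metric in metrics:
        mat = np.stack([b.features[metric] for b in train])
        n_features = mat.shape[1]
        t_arr, p_arr = _column_tests(mat[case_idx], mat[ctrl_idx], method)
        thr = alpha / n_features if correction == "bonferroni" else alpha
        kept = [(j, float(t_arr[j]), float(p_arr[j]))
                for j in np.flatnonzero(p_arr < thr)]
        per_metric[metric] = kept
        j_min = int(np.argmin(p_arr))
        if best is None or p_arr[j_min] < best[0]:
            best = (float(p_arr[j_min]), metric, j_min, float(t_arr[j_min]))
    if sum(len(v) for v in per_metric.values()) == 0 and best is not None:
        p, metric, j, t = best
        warnings.warn("no feature passed selection in any metric; keeping the "
                      "single smallest-p feature", stacklevel=2)
        per_metric[metric] = [(j, t, p)]
    return SelectionResult(per_metric=per_metric, alpha=alpha)


def fuse(bundle: FeatureBundle, selection: SelectionResult,
         metrics: tuple[str, ...] | None = None) -> np.ndarray:
    """Concatenate the selected features in fixed metric order."""
    if metrics is None:
        metrics = tuple(m for m in METRIC_ORDER if m in selection.per_metric)
    parts = []
    for metric in metrics:
        idx = selection.indices(metric)
        if idx:
            parts.append(bundle.features[metric][idx])
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def standardize(train_matrix: np.ndarray,
                apply_to: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Per-feature z-scoring with training-fold parameters.

    Returns (scaled training matrix, scaled apply_to rows, means, sds).
    ``apply_to`` (e.g. the held-out subject) is scaled with the *training*
    parameters so no information leaks out of the fold. Zero-SD features
    have their SD clamped to 1 (the feature becomes 0 after centring).
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.shape[0] < 2:
        raise ValueError("need at least 2 training subjects to standardize")
    means = train_matrix.mean(axis=0)
    sds = train_matrix.std(axis=0, ddof=0)
    clamped = sds == 0
    if clamped.any():
        warnings.warn(f"{int(clamped.sum())} constant features: SD clamped "
                      "to 1", stacklevel=2)
    sds = np.where(clamped, 1.0, sds)
    scaled = (train_matrix - means) / sds
    scaled_apply = None
    if apply_to is not None:
        apply_to = np.atleast_2d(np.asarray(apply_to, dtype=float))
        scaled_apply = (apply_to - means) / sds
    return scaled, scaled_apply, means, sds


# ---------------------------------------------------------------------------
# SVM with grid search


def grid_search_svm(train_matrix: np.ndarray, labels: np.ndarray,
                    grid: SvmGrid = SvmGrid()
                    ) -> tuple[PrecomputedSVM, float, float, float]:
    """Pick (C, G) by exact inner leave-one-out accuracy on the training set.

    All ``len(C) x len(G)`` pairs are scored; ties are broken toward the
    smallest C, then the smallest G. Returns the model refit on the whole
    training set with the winner, plus (C, G, inner accuracy).
    """
    X = np.asarray(train_matrix, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if X.shape[0] != n:
        raise ValueError("matrix/labels length mismatch")
    gram = X @ X.T
    cs = grid.c_values
    gs = grid.g_values
    acc = np.zeros((len(cs), len(gs)))
    idx = np.arange(n)
    for i in range(n):
        if len(np.unique(y[idx != i])) < 2:
            raise ValueError("inner fold degenerate: single class")
    for jg, g in enumerate(gs):
        K = sigmoid_kernel(gram, g, grid.coef0)
        # pre-slice the kernel once per G; reused across all C values
        subs = [(np.ascontiguousarray(K[np.ix_(idx != i, idx != i)]),
                 np.ascontiguousarray(K[i, idx != i][None, :]),
                 y[idx != i]) for i in range(n)]
        for jc, c in enumerate(cs):
            correct = 0
            for i in range(n):
                sub_k, row_k, sub_y = subs[i]
                correct += fit_predict_label(sub_k, sub_y, row_k, c) == y[i]
            acc[jc, jg] = correct / n
    best_flat = int(np.argmax(acc))  # first max in (C, G) lexicographic order
    jc, jg = np.unravel_index(best_flat, acc.shape)
    best_c, best_g = float(cs[jc]), float(gs[jg])
    model = PrecomputedSVM(C=best_c).fit(sigmoid_kernel(gram, best_g,
                                                        grid.coef0), y)
    return model, best_c, best_g, float(acc[jc, jg])


# ---------------------------------------------------------------------------
# LOOCV


def _resolve_metrics(bundles: list[FeatureBundle],
                     metrics: tuple[str, ...] | None) -> tuple[str, ...]:
    available = set(bundles[0].features)
    if metrics is None:
        metrics = tuple(m for m in METRIC_ORDER if m in available)
    else:
        missing = set(metrics) - available
        if missing:
            raise ValueError(f"metrics not in bundles: {sorted(missing)}")
        metrics = tuple(m for m in METRIC_ORDER if m in metrics)
    if not metrics:
        raise ValueError("no metric channels available")
    return metrics


def _labels(bundles: list[FeatureBundle]) -> np.ndarray:
    return np.array([1.0 if b.group == "case" else -1.0 for b in bundles])


def loocv(bundles: list[FeatureBundle], alpha: float = 0.05,
          grid: SvmGrid = SvmGrid(),
          metrics: tuple[str, ...] | None = None,
          selector: str = "t", mode: str = "nested",
          ) -> tuple[EvaluationSummary, list[FoldResult]]:
    """Leave-one-out evaluation of the select/fuse/scale/SVM pipeline.

    Exactly one fold per subject; everything (selection, scaling, grid
    search) is computed on the training side of each fold. ``mode='global'``
    instead fixes (C, G) by one grid search on the full cohort before
    cross-validating (optimistically biased; for protocol comparison only).
    """
    metrics = _resolve_metrics(bundles, metrics)
    n_case = sum(b.group == "case" for b in bundles)
    n_ctrl = sum(b.group == "control" for b in bundles)
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need at least 2 subjects per group")
    if mode not in ("nested", "global"):
        raise ValueError("mode must be 'nested' or 'global'")

    fixed_cg: tuple[float, float] | None = None
    if mode == "global":
        sel_all = select_features(bundles, alpha, selector, metrics)
        X_all = np.stack([fuse(b, sel_all, metrics) for b in bundles])
        X_all, _, _, _ = standardize(X_all)
        _, c_all, g_all, _ = grid_search_svm(X_all, _labels(bundles), grid)
        fixed_cg = (c_all, g_all)

    folds: list[FoldResult] = []
    for i, held in enumerate(bundles):
        train = bundles[:i] + bundles[i + 1:]
        folds.append(_run_fold(train, held, alpha=alpha, grid=grid,
                               metrics=metrics, selector=selector,
                               fixed_cg=fixed_cg))
    summary = _summarize(folds, metrics, mode)
    return summary, folds


def _run_fold(train: list[FeatureBundle], held: FeatureBundle,
              alpha: float, grid: SvmGrid, metrics: tuple[str, ...],
              selector: str,
              fixed_cg: tuple[float, float] | None = None) -> FoldResult:
    """One LOOCV fold; the held-out subject never influences the fit."""
    selection = select_features(train, alpha, selector, metrics)
    X_train = np.stack([fuse(b, selection, metrics) for b in train])
    x_test = fuse(held, selection, metrics)
    X_train, x_test, _, _ = standardize(X_train, x_test)
    y_train = _labels(train)
    if fixed_cg is None:
        model, c, g, inner = grid_search_svm(X_train, y_train, grid)
    else:
        c, g = fixed_cg
        model = PrecomputedSVM(C=c).fit(
            sigmoid_kernel(X_train @ X_train.T, g, grid.coef0), y_train)
        inner = float("nan")
    k_row = sigmoid_kernel(x_test @ X_train.T, g, grid.coef0)
    score = float(model.decision(k_row)[0])
    predicted = "case" if score > 0 else "control"
    return FoldResult(held_out=held.subject_id, selection=selection, C=c,
                      G=g, inner_accuracy=inner, index_score=score,
                      predicted=predicted, truth=held.group)


def _summarize(folds: list[FoldResult], metrics: tuple[str, ...],
               mode: str) -> EvaluationSummary:
    acc, sens, spec = confusion_metrics(folds)
    scores = {f.held_out: f.index_score for f in folds}
    truths = {f.held_out: f.truth for f in folds}
    _, _, _, auc = roc_auc(np.array([f.index_score for f in folds]),
                           np.array([f.truth == "case" for f in folds]))
    counts = pd.DataFrame(
        [{"fold": i + 1, "held_out": f.held_out,
          **{m: len(f.selection.per_metric.get(m, [])) for m in metrics}}
         for i, f in enumerate(folds)])
    return EvaluationSummary(accuracy=acc, sensitivity=sens, specificity=spec,
                             auc=auc, n_folds=len(folds), scores=scores,
                             truths=truths, fold_counts=counts, mode=mode)


# ---------------------------------------------------------------------------
# Metrics and reports


def confusion_metrics(folds: list[FoldResult]) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent.

    Sensitivity is the true-positive rate among cases, specificity the
    true-negative rate among controls. A missing class makes the
    corresponding rate NaN (flagged by warning).
    """
    if not folds:
        raise ValueError("no fold results")
    tp = sum(f.truth == "case" and f.predicted == "case" for f in folds)
    fn = sum(f.truth == "case" and f.predicted == "control" for f in folds)
    tn = sum(f.truth == "control" and f.predicted == "control" for f in folds)
    fp = sum(f.truth == "control" and f.predicted == "case" for f in folds)
    accuracy = 100.0 * (tp + tn) / len(folds)
    if tp + fn == 0 or tn + fp == 0:
        warnings.warn("a class is missing; sensitivity/specificity undefined",
                      stacklevel=2)
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    specificity = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return accuracy, sensitivity, specificity


def roc_auc(scores: np.ndarray, is_case: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve over the observed index-scores and its AUC.

    Thresholds sweep the observed scores; the AUC equals the Mann-Whitney
    statistic with ties counted 1/2. Returns (fpr, tpr, thresholds, auc).
    """
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.all() or not is_case.any():
        raise ValueError("both classes are required for a ROC curve")
    fpr, tpr, thresholds = roc_curve(is_case, scores, drop_intermediate=False)
    auc = float(roc_auc_score(is_case, scores))
    return fpr, tpr, thresholds, auc


def selection_frequency(folds: list[FoldResult], bundles: list[FeatureBundle],
                        min_count: int = 23,
                        region_names: dict[str, list[str]] | list[str] | None = None,
                        selector: str = "t") -> pd.DataFrame:
    """Regions retained in strictly more than ``min_count`` folds.

    For each reported (metric, region) the whole-cohort test statistic and p
    are recomputed, mirroring the reference report layout (Type, Region,
    P-value, T-value) plus the retention count. ``min_count=23`` reports
    regions selected in more than half of 46 folds.
    """
    counts: dict[tuple[str, int], int] = {}
    for f in folds:
        for metric, kept in f.selection.per_metric.items():
            for j, _, _ in kept:
                counts[(metric, j)] = counts.get((metric, j), 0) + 1
    case = [b for b in bundles if b.group == "case"]
    ctrl = [b for b in bundles if b.group == "control"]
    rows = []
    for (metric, j), count in sorted(counts.items()):
        if count <= min_count:
            continue
        t, p = two_sample_t(np.array([b.features[metric][j] for b in case]),
                            np.array([b.features[metric][j] for b in ctrl]),
                            method=selector)
        if isinstance(region_names, dict):
            name = region_names[metric][j]
        elif region_names is not None:
            name = region_names[j]
        else:
            name = str(j)
        rows.append({"Type": metric, "Region": name, "RegionIndex": j,
                     "Count": count, "P-value": p, "T-value": t})
    order = {m: i for i, m in enumerate(METRIC_ORDER)}
    df = pd.DataFrame(rows, columns=["Type", "Region", "RegionIndex",
                                     "Count", "P-value", "T-value"])
    if len(df):
        df = df.sort_values(by=["Type", "RegionIndex"],
                            key=lambda s: s.map(order) if s.name == "Type" else s
                            ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# CSV interop


def bundles_to_frame(bundles: list[FeatureBundle],
                     region_labels: list[str] | None = None) -> pd.DataFrame:
    """Feature table: one row per subject, columns ``metric:region``."""
    metrics = tuple(m for m in METRIC_ORDER if m in bundles[0].features)
    n_regions = len(bundles[0].features[metrics[0]])
    if region_labels is None:
        region_labels = [str(i + 1) for i in range(n_regions)]
    rows = []
    for b in bundles:
        row: dict[str, object] = {"subject_id": b.subject_id, "group": b.group}
        for m in metrics:
            for lab, v in zip(region_labels, b.features[m]):
                row[f"{m}:{lab}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_bundles(frame: pd.DataFrame) -> list[FeatureBundle]:
    """Inverse of :func:`bundles_to_frame`."""
    metric_cols: dict[str, list[str]] = {}
    for col in frame.columns:
        if ":" in col:
            metric = col.split(":", 1)[0]
            metric_cols.setdefault(metric, []).append(col)
    bundles = []
    for _, row in frame.iterrows():
        features = {m: row[cols].to_numpy(dtype=float)
                    for m, cols in metric_cols.items()}
        bundles.append(FeatureBundle(subject_id=str(row["subject_id"]),
                                     group=str(row["group"]),
                                     features=features))
    return bundles
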