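"""Stage classification, wrapper feature selection and anomaly screening.

Subjects are classified into hyperbaric stages from the nine baseline-
referenced features (F_R, the four time parameters, the four OSP frequency
parameters) with four classifier families — LDA, a medium-Gaussian SVM
(kernel scale sqrt(n_features), box constraint 1), cosine-distance KNN
(k = 10), and a discriminant ensemble (random-subspace LDA, 30 learners,
subspace dimension ceil(n_features / 2)).  Validation is leave-one-subject-
out: the held-out subject contributes one feature vector per member stage
(two cases per subject in a two-class task), training features are z-scored
with training-fold statistics, and accuracy is 100 * (TP + TN) / cases.

The wrapper selector grows the feature set greedily, re-evaluating every
remaining feature by full leave-one-out at each step (ties broken uniformly
at random under the given seed), producing a 9-point accuracy curve per
(task, family).

Anomaly screening accumulates misclassifications: for a pair of stages every
subject has 72 result slots (2 classes x 4 families x 9 feature counts);
only cells whose accuracy strictly exceeds 70% count, and the subjects with
the largest accumulated miss counts are flagged as responding anomalously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = ["ClassTask", "CLASS_TASKS", "FEATURES", "FAMILIES",
           "SubspaceDiscriminantEnsemble", "make_classifier", "accuracy",
           "build_task_data", "loo_evaluate", "wrapper_select",
           "run_all_cells", "anomaly_scan", "LooResult", "AnomalyReport"]

#: canonical feature order (ratio features vs the 1D baseline)
FEATURES = ("f_r", "nn_median", "nn_iqr", "rmssd", "pnn50",
            "p_r", "p_perp", "p_lf_perp", "p_hf_perp")

FAMILIES = ("LDA", "SVM", "KNN", "DEC")


@dataclass(frozen=True)
class ClassTask:
    """A stage-identification task; each class is a group of stages."""

    name: str
    classes: tuple[tuple[str, ...], ...]

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(s for grp in self.classes for s in grp)


CLASS_TASKS = {
    "C.3D-5": ClassTask("C.3D-5", (("3D",), ("5",))),
    "C.5-3A": ClassTask("C.5-3A", (("5",), ("3A",))),
    "C.5-1A": ClassTask("C.5-1A", (("5",), ("1A",))),
    "C.3A-1A": ClassTask("C.3A-1A", (("3A",), ("1A",))),
    "C.3DA-5-1A": ClassTask("C.3DA-5-1A", (("3D", "3A"), ("5",), ("1A",))),
}


class SubspaceDiscriminantEnsemble:
    """Random-subspace ensemble of closed-form pooled-covariance LDAs.

    Equivalent in structure to the MATLAB "subspace discriminant" preset:
    ``n_estimators`` linear discriminants, each trained on a random feature
    subspace of dimension ``ceil(p / 2)``; prediction is by vote.  The base
    learner is solved in closed form (class means + ridge-stabilised pooled
    covariance), which keeps the very large number of leave-one-out fits in
    the wrapper and anomaly suites cheap.
    """

    def __init__(self, n_estimators: int = 30, subspace_dim: int | None = None,
                 ridge: float = 1e-6, random_state: int = 0):
        self.n_estimators = n_estimators
        self.subspace_dim = subspace_dim
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, x: np.ndarray, y: np.ndarray):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n, p = x.shape
        k = self.classes_.size
        dim = self.subspace_dim or max(1, int(np.ceil(p / 2)))
        dim = min(dim, p)
        rng = np.random.default_rng(self.random_state)
        # class means and full pooled covariance once; per-learner subspaces
        # are slices of them, solved in one batched call
        means = np.stack([x[y == c].mean(axis=0) for c in self.classes_])
        pooled = np.zeros((p, p))
        for c, mu in zip(self.classes_, means):
            d = x[y == c] - mu
            pooled += d.T @ d
        pooled /= max(1, n - k)
        cols = np.stack([rng.choice(p, size=dim, replace=False)
                         for _ in range(self.n_estimators)])
        cov = pooled[cols[:, :, None], cols[:, None, :]]  # (n_est, dim, dim)
        tr = np.trace(cov, axis1=1, axis2=2) / dim
        cov = cov + (self.ridge * np.maximum(tr, 1e-12))[:, None, None] \
            * np.eye(dim)
        mu_sub = means[:, cols].transpose(1, 0, 2)        # (n_est, k, dim)
        w = np.linalg.solve(cov, mu_sub.transpose(0, 2, 1)).transpose(0, 2, 1)
        priors = np.log(np.array([(y == c).mean() for c in self.classes_]))
        b = -0.5 * np.sum(w * mu_sub, axis=2) + priors    # (n_est, k)
        self._cols, self._w, self._b = cols, w, b
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xs = x[:, self._cols]                             # (n, n_est, dim)
        scores = np.einsum("nej,ekj->nek", xs, self._w) + self._b
        idx = np.argmax(scores, axis=2)                   # (n, n_est)
        votes = np.apply_along_axis(
            lambda r: np.bincount(r, minlength=self.classes_.size), 1, idx)
        return self.classes_[np.argmax(votes, axis=1)]


def make_classifier(family: str, n_features: int, seed: int = 0):
    """One classifier instance per family (MATLAB-preset-equivalent defaults)."""
    if family == "LDA":
        return LinearDiscriminantAnalysis()
    if family == "SVM":
        # medium Gaussian: kernel scale sqrt(P) => gamma = 1 / P
        return SVC(C=1.0, kernel="rbf", gamma=1.0 / max(n_features, 1))
    if family == "KNN":
        return KNeighborsClassifier(n_neighbors=10, metric="cosine",
                                    algorithm="brute")
    if family == "DEC":
        return SubspaceDiscriminantEnsemble(random_state=seed)
    raise ValueError(f"unknown classifier family {family!r}")


def accuracy(correct) -> float:
    """Percent accuracy, 100 * (TP + TN) / total cases."""
    correct = np.asarray(correct, dtype=bool)
    if correct.size == 0:
        raise ValueError("no cases")
    return 100.0 * correct.mean()


def build_task_data(ratios: pd.DataFrame, task: ClassTask,
                    features=FEATURES,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix / labels / subject ids for one task.

    A subject missing any member stage (or with a missing feature value
    there) is excluded from the task.  Rows are ordered subject-major; the
    label is the index of the class group the row's stage belongs to.
    """
    rows, labels, subjects = [], [], []
    feats = list(features)
    for sid in ratios.index.get_level_values("subject").unique():
        grp = ratios.xs(sid, level="subject")
        vecs, labs = [], []
        ok = True
        for ci, cls in enumerate(task.classes):
            for stage in cls:
                if stage not in grp.index:
                    ok = False
                    break
                v = grp.loc[stage, feats].to_numpy(dtype=float)
                if not np.all(np.isfinite(v)):
                    ok = False
                    break
                vecs.append(v)
                labs.append(ci)
            if not ok:
                break
        if ok:
            rows.extend(vecs)
            labels.extend(labs)
            subjects.extend([sid] * len(vecs))
    if not rows:
        raise ValueError(f"no eligible subjects for task {task.name}")
    return (np.asarray(rows, dtype=float), np.asarray(labels),
            np.asarray(subjects))


@dataclass
class LooResult:
    accuracy: float
    correct: np.ndarray        # per-case flags, aligned with rows
    subjects: np.ndarray


def loo_evaluate(x: np.ndarray, y: np.ndarray, subjects: np.ndarray,
                 family: str, feature_idx=None, seed: int = 0) -> LooResult:
    """Leave-one-subject-out evaluation of one (family, feature-set) cell.

    Features are z-scored with the training fold's statistics; the held-out
    subject's rows are never part of the training set (guarded by
    assertion).
    """
    x = np.asarray(x, dtype=float)
    if feature_idx is not None:
        x = x[:, list(feature_idx)]
    correct = np.zeros(y.size, dtype=bool)
    for sid in np.unique(subjects):
        test = subjects == sid
        train = ~test
        assert not np.any(subjects[train] == sid), "LOO leakage"
        mu = x[train].mean(axis=0)
        sd = x[train].std(axis=0)
        sd[sd == 0] = 1.0
        xt = (x[train] - mu) / sd
        xh = (x[test] - mu) / sd
        if family == "KNN":
            pred = _knn_cosine_predict(xt, y[train], xh)
        else:
            clf = make_classifier(family, x.shape[1], seed)
            clf.fit(xt, y[train])
            pred = clf.predict(xh)
        correct[test] = pred == y[test]
    return LooResult(accuracy=accuracy(correct), correct=correct,
                     subjects=np.asarray(subjects))


def _knn_cosine_predict(xt: np.ndarray, yt: np.ndarray, xh: np.ndarray,
                        k: int = 10) -> np.ndarray:
    """Vectorised cosine-distance k-NN, identical to the sklearn classifier.

    Inlined on the hot leave-one-out path (tens of thousands of tiny fits in
    the wrapper/anomaly suites); parity with ``KNeighborsClassifier`` is
    asserted in the tests.
    """
    k = min(k, xt.shape[0])
    nt = xt / np.maximum(np.linalg.norm(xt, axis=1, keepdims=True), 1e-30)
    nh = xh / np.maximum(np.linalg.norm(xh, axis=1, keepdims=True), 1e-30)
    dist = 1.0 - nh @ nt.T
    nn = np.argpartition(dist, k - 1, axis=1)[:, :k]
    classes = np.unique(yt)
    lab = np.searchsorted(classes, yt[nn])
    counts = np.apply_along_axis(
        lambda r: np.bincount(r, minlength=classes.size), 1, lab)
    return classes[np.argmax(counts, axis=1)]


@dataclass
class WrapperResult:
    family: str
    order: list[int]                  # selected feature indices, in order
    curve: list[float]                # accuracy at 1..9 features
    cells: list[LooResult] = field(default_factory=list)


def wrapper_select(x: np.ndarray, y: np.ndarray, subjects: np.ndarray,
                   family: str, seed: int = 0) -> WrapperResult:
    """Greedy forward wrapper selection with full LOO at every step.

    At each step every remaining feature is joined to the selected set and
    evaluated; the best joins the set (ties broken uniformly at random with
    ``seed``).  Returns the selection order, the accuracy curve and the
    per-cell LOO results for counts 1..n_features.
    """
    rng = np.random.default_rng(seed)
    p = x.shape[1]
    selected: list[int] = []
    remaining = list(range(p))
    curve: list[float] = []
    cells: list[LooResult] = []
    while remaining:
        results = [(fi, loo_evaluate(x, y, subjects, family,
                                     selected + [fi], seed))
                   for fi in remaining]
        best_acc = max(r.accuracy for _, r in results)
        ties = [(fi, r) for fi, r in results
                if np.isclose(r.accuracy, best_acc)]
        fi, res = ties[rng.integers(len(ties))]
        selected.append(fi)
        remaining.remove(fi)
        curve.append(res.accuracy)
        cells.append(res)
    return WrapperResult(family=family, order=selected, curve=curve,
                         cells=cells)


def run_all_cells(ratios: pd.DataFrame, task: ClassTask, seed: int = 0,
                  families=FAMILIES) -> dict[str, WrapperResult]:
    """Wrapper selection for every family on one task."""
    x, y, subjects = build_task_data(ratios, task)
    return {fam: wrapper_select(x, y, subjects, fam, seed)
            for fam in families}


@dataclass
class AnomalyReport:
    counts: pd.Series            # per-subject misclassification count
    n_qualifying: int            # qualifying cells (accuracy > threshold)
    max_count: int               # countable results per subject
    flagged: list                # subjects above the count cut
    threshold: float
    flag_count: int


def anomaly_scan(results: dict[str, WrapperResult] |
                 list[dict[str, WrapperResult]],
                 threshold: float = 70.0,
                 flag_count: int = 20) -> AnomalyReport:
    """Accumulate misclassifications over qualifying classifier cells.

    ``results`` is the cell grid of one task pair (or a list of grids, whose
    counts accumulate, as when pooling the two richest pairs).  A cell
    qualifies iff its accuracy strictly exceeds ``threshold`` percent; each
    qualifying cell contributes one countable result per (subject, class)
    case.  Subjects with more than ``flag_count`` accumulated misses are
    flagged.
    """
    grids = results if isinstance(results, list) else [results]
    counts: dict = {}
    n_qual = 0
    max_count: dict = {}
    for grid in grids:
        for wr in grid.values():
            for cell in wr.cells:
                if cell.accuracy <= threshold:
                    continue
                n_qual += 1
                for sid, ok in zip(cell.subjects, cell.correct):
                    counts[sid] = counts.get(sid, 0) + (0 if ok else 1)
                    max_count[sid] = max_count.get(sid, 0) + 1
    series = pd.Series(counts, dtype=int).sort_values(ascending=False)
    flagged = [sid for sid, c in series.items() if c > flag_count]
    return AnomalyReport(counts=series, n_qualifying=n_qual,
                         max_count=max(max_count.values()) if max_count else 0,
                         flagged=flagged, threshold=threshold,
                         flag_count=flag_count)
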