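"""Classification pipelines, cross-validation harnesses and statistics.

The main pipeline is xDAWN(F=3) -> augmented covariance -> tangent-space
mapping -> L2 logistic regression, evaluated either across subjects
(leave-one-subject-out, LOSO) or within subjects (stratified 4-fold per
subject). Five comparison pipelines (vectorized LR, covariance+LR,
covariance+TS+LR, xDAWN-covariance+LR, CSP+LR) share the same harness.
Every supervised stage — xDAWN filters and prototypes, the tangent-space
reference point, CSP filters, the classifier — is fitted on training
folds only and applied frozen to the held-out fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix as _sk_confusion,
    matthews_corrcoef,
    precision_recall_curve,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .dataset import EpochSet
from .geometry import geometric_mean, log_map, vectorize_tangent
from .xdawn import SPDMatrix, augment_trial, class_average, covariance, fit_xdawn

#: Scalp-region electrode triads used in the spatial-information analysis.
REGION_TRIADS: dict[str, tuple[str, str, str]] = {
    "occipital": ("O1", "Oz", "O2"),
    "parietal": ("P3", "Pz", "P4"),
    "central": ("C3", "Cz", "C4"),
    "frontal": ("F3", "Fz", "F4"),
}

_KNOWN_STAGES = ("vectorize", "covariance", "xdawn", "csp", "tangent_space",
                 "logistic_regression")


@dataclass(frozen=True)
class PipelineSpec:
    """Declarative description of a classification pipeline.

    ``stages`` is an ordered tuple drawn from {vectorize, covariance,
    xdawn, csp, tangent_space, logistic_regression}; the classifier must
    come last and tangent_space requires a covariance-producing stage
    (covariance or xdawn) upstream.
    """

    stages: tuple[str, ...]
    n_filters: int = 3
    estimator: str = "oas"
    n_csp_components: int = 4
    C: float = 1.0
    source_space: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        unknown = [s for s in self.stages if s not in _KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        if not self.stages or self.stages[-1] != "logistic_regression":
            raise ValueError("a classifier (logistic_regression) must be last")
        if "tangent_space" in self.stages:
            pos = self.stages.index("tangent_space")
            if not any(s in ("covariance", "xdawn") for s in self.stages[:pos]):
                raise ValueError("tangent_space requires covariance or xdawn upstream")
        if not self.name:
            object.__setattr__(self, "name", "_".join(self.stages))


#: The six comparison pipelines, main pipeline last.
STANDARD_PIPELINES: dict[str, PipelineSpec] = {
    "vec_lr": PipelineSpec(("vectorize", "logistic_regression"), name="vec_lr"),
    "cov_lr": PipelineSpec(("covariance", "logistic_regression"), name="cov_lr"),
    "cov_ts_lr": PipelineSpec(("covariance", "tangent_space", "logistic_regression"),
                              name="cov_ts_lr"),
    "xdawn_cov_lr": PipelineSpec(("xdawn", "logistic_regression"), name="xdawn_cov_lr"),
    "csp_lr": PipelineSpec(("csp", "logistic_regression"), name="csp_lr"),
    "xdawn_ts_lr": PipelineSpec(("xdawn", "tangent_space", "logistic_regression"),
                                name="xdawn_ts_lr"),
}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _trial_covariances(data: np.ndarray, estimator: str) -> list[SPDMatrix]:
    return [covariance(trial, estimator=estimator) for trial in data]


class _XdawnStage:
    """xDAWN filters + prototypes fitted on training trials only."""

    def __init__(self, n_filters: int, estimator: str):
        self.n_filters, self.estimator = n_filters, estimator

    def fit(self, epochs: EpochSet) -> "_XdawnStage":
        self.bank_ = fit_xdawn(epochs, self.n_filters)
        self.prototypes_ = (class_average(epochs, 0), class_average(epochs, 1))
        return self

    def transform(self, data: np.ndarray) -> list[SPDMatrix]:
        return [covariance(augment_trial(x, self.bank_, self.prototypes_),
                           estimator=self.estimator)
                for x in data]


class _CSPStage:
    """Common spatial patterns with paired component selection.

    Filters are generalized eigenvectors of (class-0 mean covariance,
    pooled mean covariance); components are taken in pairs from the two
    ends of the eigenvalue spectrum and features are log-variances of
    the filtered signals.
    """

    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, epochs: EpochSet) -> "_CSPStage":
        if self.n_components > epochs.n_channels:
            raise ValueError(
                f"n_components ({self.n_components}) exceeds channel count "
                f"({epochs.n_channels})"
            )
        covs = {k: np.mean([c.values for c in _trial_covariances(
            epochs.data[epochs.labels == k], "empirical")], axis=0)
            for k in (0, 1)}
        import scipy.linalg
        pooled = covs[0] + covs[1]
        # ridge guard for rank-deficient (e.g. noise-free) signals
        if np.linalg.cond(pooled) > 1e12:
            pooled = pooled + 1e-10 * (np.trace(pooled) / pooled.shape[0]) * np.eye(
                pooled.shape[0])
        evals, evecs = scipy.linalg.eigh(covs[0], pooled)
        order = np.argsort(evals)  # ascending
        picks: list[int] = []
        lo, hi = 0, len(order) - 1
        while len(picks) < self.n_components:
            picks.append(order[hi]); hi -= 1
            if len(picks) < self.n_components:
                picks.append(order[lo]); lo += 1
        self.filters_ = evecs[:, picks]
        return self

    def transform(self, data: np.ndarray) -> np.ndarray:
        filtered = np.einsum("cf,ncs->nfs", self.filters_, data)
        return np.log(filtered.var(axis=-1) + 1e-300)


class _TangentStage:
    def fit(self, covs: list[SPDMatrix]) -> "_TangentStage":
        self.ref_ = geometric_mean(covs)
        return self

    def transform(self, covs: list[SPDMatrix]) -> np.ndarray:
        return np.vstack([
            vectorize_tangent(log_map(c, self.ref_), self.ref_).values for c in covs
        ])


def _unroll(covs: list[SPDMatrix]) -> np.ndarray:
    return np.vstack([c.values.ravel() for c in covs])


class Pipeline:
    """A fitted realization of a :class:`PipelineSpec`."""

    def __init__(self, spec: PipelineSpec):
        self.spec = spec

    # feature extraction shared by fit and predict
    def _features(self, epochs: EpochSet, fitting: bool) -> np.ndarray:
        spec = self.spec
        x: object = epochs.data
        for stage in spec.stages[:-1]:
            if stage == "vectorize":
                x = np.asarray(x).reshape(len(epochs.data), -1)
            elif stage == "covariance":
                x = _trial_covariances(np.asarray(x), spec.estimator)
            elif stage == "xdawn":
                if fitting:
                    self._xdawn = _XdawnStage(spec.n_filters, spec.estimator).fit(epochs)
                x = self._xdawn.transform(np.asarray(x))
            elif stage == "csp":
                if fitting:
                    self._csp = _CSPStage(spec.n_csp_components).fit(epochs)
                x = self._csp.transform(np.asarray(x))
            elif stage == "tangent_space":
                if fitting:
                    self._tangent = _TangentStage().fit(x)
                x = self._tangent.transform(x)
        if isinstance(x, list):  # covariances not mapped: unroll for the LR
            x = _unroll(x)
        return np.asarray(x, dtype=float)

    def fit(self, epochs: EpochSet) -> "Pipeline":
        features = self._features(epochs, fitting=True)
        # L2 regularization is the sklearn default (l1_ratio=0)
        self._clf = LogisticRegression(C=self.spec.C, solver="lbfgs", max_iter=2000)
        self._clf.fit(features, epochs.labels)
        return self

    def predict(self, epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
        """Return (predicted labels, decision scores) for held-out epochs."""
        features = self._features(epochs, fitting=False)
        return self._clf.predict(features), self._clf.decision_function(features)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def evaluate_metrics(labels: np.ndarray, scores: np.ndarray,
                     predictions: np.ndarray) -> dict:
    """Binary-classification metric bundle.

    Returns confusion matrix (rows true, cols predicted), accuracy, MCC
    (0 when a confusion-matrix marginal is zero), ROC points with
    trapezoidal AUC, precision-recall points with step-wise average
    precision.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    predictions = np.asarray(predictions, dtype=int)
    if not (len(labels) == len(scores) == len(predictions)):
        raise ValueError("labels, scores and predictions must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in labels")
    cm = _sk_confusion(labels, predictions, labels=[0, 1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on zero marginals
        mcc = float(matthews_corrcoef(labels, predictions))
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(labels, scores)
    ap = float(average_precision_score(labels, scores))
    return {
        "confusion": cm,
        "accuracy": float((predictions == labels).mean()),
        "mcc": mcc,
        "roc": (fpr, tpr),
        "auc": auc,
        "pr": (precision, recall),
        "ap": ap,
    }


# ---------------------------------------------------------------------------
# Cross-validation reports
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold_id: str
    test_index: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray

    @property
    def accuracy(self) -> float:
        return float((self.y_true == self.y_pred).mean())

    @property
    def confusion(self) -> np.ndarray:
        return _sk_confusion(self.y_true, self.y_pred, labels=[0, 1])


@dataclass
class CVReport:
    """Per-fold predictions plus pooled metrics for one pipeline run."""

    scheme: str
    pipeline: str
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1)) if len(self.folds) > 1 else 0.0

    def pooled(self) -> dict:
        """Metrics over all folds' test trials pooled (raw counts summed)."""
        y = np.concatenate([f.y_true for f in self.folds])
        s = np.concatenate([f.scores for f in self.folds])
        p = np.concatenate([f.y_pred for f in self.folds])
        return evaluate_metrics(y, s, p)

    def check_fold_partition(self, n_trials: int) -> bool:
        """Fold test sets are disjoint and cover all trials."""
        all_idx = np.concatenate([f.test_index for f in self.folds])
        return len(all_idx) == n_trials and len(np.unique(all_idx)) == n_trials


def _run_folds(epochs: EpochSet, spec: PipelineSpec,
               folds: Iterable[tuple[str, np.ndarray, np.ndarray]],
               scheme: str) -> CVReport:
    report = CVReport(scheme=scheme, pipeline=spec.name)
    for fold_id, train_idx, test_idx in folds:
        model = Pipeline(spec).fit(epochs.take(train_idx))
        test = epochs.take(test_idx)
        y_pred, scores = model.predict(test)
        report.folds.append(FoldResult(
            fold_id=fold_id, test_index=test_idx,
            y_true=test.labels, y_pred=y_pred, scores=scores,
        ))
    return report


def run_loso(epochs: EpochSet, spec: PipelineSpec) -> CVReport:
    """Leave-one-subject-out: one fold per subject, trained on the rest."""
    subjects = epochs.subjects
    if len(subjects) < 2:
        raise ValueError(
            "LOSO needs at least 2 subjects; use run_kfold_per_subject for "
            "single-subject data"
        )
    folds = []
    for subj in subjects:
        test_idx = np.flatnonzero(epochs.subject_ids == subj)
        train_idx = np.flatnonzero(epochs.subject_ids != subj)
        folds.append((f"subject_{subj}", train_idx, test_idx))
    return _run_folds(epochs, spec, folds, scheme="LOSO")


def run_kfold_per_subject(epochs: EpochSet, spec: PipelineSpec, k: int = 4,
                          seed: int = 0) -> CVReport:
    """Stratified k-fold within each subject independently.

    Fold-level accuracies (one per subject x fold) are retained as the
    sampling units for the distribution comparisons.
    """
    folds = []
    for subj in epochs.subjects:
        subj_idx = np.flatnonzero(epochs.subject_ids == subj)
        y = epochs.labels[subj_idx]
        counts = np.bincount(y, minlength=2)
        if counts.min() < k:
            raise ValueError(
                f"subject {subj} has only {counts.min()} trials in its smallest "
                f"class; {k}-fold CV needs at least {k}"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for i, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            folds.append((f"subject_{subj}_fold_{i}", subj_idx[tr], subj_idx[te]))
    return _run_folds(epochs, spec, folds, scheme=f"{k}-fold-per-subject")


# ---------------------------------------------------------------------------
# Higher-level analyses
# ---------------------------------------------------------------------------

def source_space_epochs(sim, alpha: float | None = None) -> EpochSet:
    """Region-averaged sLORETA activations of every trial as an EpochSet.

    The inverse operator is deterministic given the lead field, so this
    unsupervised projection may be applied to the whole dataset before
    cross-validation without leaking label information.
    """
    from .sloreta import apply_inverse, average_by_region, default_alpha, make_inverse

    lf = sim.leadfield
    inv = make_inverse(lf, default_alpha(lf) if alpha is None else alpha)
    rows = []
    for trial in sim.epochs.data:
        est = apply_inverse(inv, trial)
        rows.append(average_by_region(est, lf).activation)
    region_ids = np.unique(lf.region_labels)
    return EpochSet(
        data=np.stack(rows),
        labels=sim.epochs.labels,
        subject_ids=sim.epochs.subject_ids,
        channel_names=tuple(f"region_{r}" for r in region_ids),
        sampling_rate=sim.epochs.sampling_rate,
        t0_offset=sim.epochs.t0_offset,
    )


def run_comparison_suite(epochs: EpochSet, source_sim=None,
                         schemes: Sequence[str] = ("loso",),
                         k: int = 4, seed: int = 0) -> pd.DataFrame:
    """Run all six standard pipelines for each scheme (and space).

    Returns a tidy table with one row per (pipeline, scheme, space) and
    a ``report`` column holding the full :class:`CVReport`.
    """
    spaces: list[tuple[str, EpochSet]] = [("sensor", epochs)]
    if source_sim is not None:
        spaces.append(("source", source_space_epochs(source_sim)))
    rows = []
    for space, eps in spaces:
        for scheme in schemes:
            for name, base in STANDARD_PIPELINES.items():
                # clamp stage sizes to the channel (or region) count
                spec = PipelineSpec(
                    base.stages,
                    n_filters=min(base.n_filters, eps.n_channels),
                    estimator=base.estimator,
                    n_csp_components=min(base.n_csp_components, eps.n_channels),
                    C=base.C, name=base.name)
                if scheme == "loso":
                    report = run_loso(eps, spec)
                elif scheme == "kfold":
                    report = run_kfold_per_subject(eps, spec, k=k, seed=seed)
                else:
                    raise ValueError(f"unknown scheme '{scheme}'")
                rows.append({
                    "pipeline": name, "scheme": scheme, "space": space,
                    "mean_accuracy": report.mean_accuracy,
                    "sd_accuracy": report.sd_accuracy,
                    "auc": report.pooled()["auc"],
                    "mcc": report.pooled()["mcc"],
                    "report": report,
                })
    return pd.DataFrame(rows)


def csp_features(epochs: EpochSet, n_components: int = 4) -> pd.DataFrame:
    """Fit CSP on the full set and return per-trial log-variance features."""
    for k in (0, 1):
        if not np.any(epochs.labels == k):
            raise ValueError(f"class {k} absent")
    stage = _CSPStage(n_components).fit(epochs)
    feats = stage.transform(epochs.data)
    df = pd.DataFrame(feats, columns=[f"csp_{i}" for i in range(n_components)])
    df["label"] = epochs.labels
    df["subject"] = epochs.subject_ids
    return df


def forward_electrode_selection(epochs: EpochSet, spec: PipelineSpec,
                                max_k: int | None = None) -> tuple[list[str], np.ndarray]:
    """Greedy forward selection of electrodes by LOSO accuracy.

    At each step the electrode whose addition maximizes LOSO accuracy of
    ``spec`` restricted to the selected set is added; ties go to the
    earlier montage position. Returns the selection order and the
    accuracy-vs-k curve.
    """
    from .preprocessing import select_channels

    names = list(epochs.channel_names)
    if max_k is None:
        max_k = len(names)
    if max_k > len(names):
        raise ValueError("max_k exceeds channel count")
    selected: list[str] = []
    curve = []
    spec_eff = spec
    for step in range(max_k):
        best_name, best_acc = None, -np.inf
        for cand in names:
            if cand in selected:
                continue
            subset = selected + [cand]
            n_filt = min(spec.n_filters, len(subset))
            spec_eff = PipelineSpec(spec.stages, n_filters=n_filt,
                                    estimator=spec.estimator,
                                    n_csp_components=min(spec.n_csp_components, len(subset)),
                                    C=spec.C, name=spec.name)
            acc = run_loso(select_channels(epochs, subset), spec_eff).mean_accuracy
            if acc > best_acc + 1e-12:
                best_name, best_acc = cand, acc
        selected.append(best_name)
        curve.append(best_acc)
    return selected, np.asarray(curve)


def region_triad_analysis(epochs: EpochSet, spec: PipelineSpec,
                          triads: dict[str, tuple[str, ...]] | None = None) -> pd.Series:
    """LOSO accuracy of ``spec`` restricted to each scalp-region triad."""
    from .preprocessing import select_channels

    if triads is None:
        triads = REGION_TRIADS
    out = {}
    for region, chans in triads.items():
        eff = PipelineSpec(spec.stages, n_filters=min(spec.n_filters, len(chans)),
                           estimator=spec.estimator,
                           n_csp_components=min(spec.n_csp_components, len(chans)),
                           C=spec.C, name=spec.name)
        out[region] = run_loso(select_channels(epochs, list(chans)), eff).mean_accuracy
    return pd.Series(out, name="loso_accuracy")


def compare_accuracy_distributions(report_a: CVReport, report_b: CVReport) -> dict:
    """Two-sided Mann-Whitney U test on fold-level accuracies."""
    a, b = report_a.fold_accuracies, report_b.fold_accuracies
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 fold accuracies per report")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all fold accuracies tied across both groups; p = 1")
        return {"U": len(a) * len(b) / 2.0, "p": 1.0, "direction": "tied",
                "mean_a": float(a.mean()), "mean_b": float(b.mean())}
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    if a.mean() > b.mean():
        direction = "a>b"
    elif a.mean() < b.mean():
        direction = "a<b"
    else:
        direction = "tied"
    return {"U": float(res.statistic), "p": float(res.pvalue),
            "direction": direction,
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}


def permutation_null(epochs: EpochSet, spec: PipelineSpec, n_permutations: int,
                     seed: int = 0, scheme: str = "loso", k: int = 4) -> np.ndarray:
    """Mean CV accuracies under label permutation (chance-level reference).

    Labels are permuted within each subject so that the subject/class
    bookkeeping (and class balance) is preserved.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_permutations):
        labels = epochs.labels.copy()
        for subj in epochs.subjects:
            idx = np.flatnonzero(epochs.subject_ids == subj)
            labels[idx] = rng.permutation(labels[idx])
        permuted = EpochSet(
            data=epochs.data, labels=labels, subject_ids=epochs.subject_ids,
            channel_names=epochs.channel_names,
            sampling_rate=epochs.sampling_rate, t0_offset=epochs.t0_offset,
        )
        if scheme == "loso":
            report = run_loso(permuted, spec)
        else:
            report = run_kfold_per_subject(permuted, spec, k=k,
                                           seed=int(rng.integers(2**31)))
        out.append(report.mean_accuracy)
    return np.asarray(out)
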