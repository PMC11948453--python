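"""Gaussian-kernel SVM classification of translocation events.

Events are represented by three features — fractional blockage I_B,
log10 of the dwell time in microseconds, and the blocked-level RMS — and
classified by a one-vs-one support vector machine with a Gaussian kernel
K(x, y) = exp(-||x - y||^2 / s^2) at kernel scale s = 2 on z-scored
features.  Model selection and reporting follow stratified 5-fold
cross-validation with the standardization refit inside each training fold.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .simulate import CLASS_CODES

__all__ = [
    "FEATURE_NAMES",
    "LabeledFeatureSet",
    "SVMConfig",
    "EvalReport",
    "SVMArtifact",
    "build_features",
    "balance_classes",
    "train_svm",
    "cross_validate",
    "predict",
    "roc_auc",
    "structural_feature_rate",
]

FEATURE_NAMES = ("I_B", "log10_tD", "i_rms_nA")
SCHEMA_VERSION = 1

#: integer code of the high-i_rms (structural-feature / mtDNA) class
MTDNA_CODE = CLASS_CODES["mtDNA"]


@dataclass
class LabeledFeatureSet:
    """Feature matrix (I_B, log10_tD, i_rms) with integer class labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple = FEATURE_NAMES

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError("X must be (n, n_features)")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y length mismatch")
        if not np.isfinite(self.X).all():
            raise ValueError("features contain missing or non-finite values")
        if not set(np.unique(self.y)) <= set(CLASS_CODES.values()):
            raise ValueError(f"labels must be a subset of {set(CLASS_CODES.values())}")

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def __len__(self) -> int:
        return self.X.shape[0]


def build_features(events, label=None) -> LabeledFeatureSet:
    """Build the three-feature representation from events.

    ``events`` may be a list of :class:`~porecount.detect.TranslocationEvent`
    (with ``label`` giving their common class), a per-class feature table
    from the generator (columns I_B, t_D_us, i_rms_nA, label), or a list of
    such tables.  Dwell times enter as log10(t_D / 1 us) to tame the
    exponential range of the dwell distribution.
    """
    if isinstance(events, (list, tuple)) and events and isinstance(events[0], pd.DataFrame):
        events = pd.concat(events, ignore_index=True)
    if isinstance(events, pd.DataFrame):
        df = events
        t_d = df["t_D_us"].to_numpy(float)
        if (t_d <= 0).any():
            raise ValueError("dwell times must be positive")
        labels = df["label"]
        y = (labels.map(CLASS_CODES) if labels.dtype == object else labels).to_numpy(int)
        X = np.column_stack([df["I_B"].to_numpy(float), np.log10(t_d),
                             df["i_rms_nA"].to_numpy(float)])
        return LabeledFeatureSet(X, y)
    if label is None:
        raise ValueError("label required for a bare event list")
    code = CLASS_CODES.get(label, label)
    rows = []
    for ev in events:
        if ev.t_D_us <= 0:
            raise ValueError("dwell times must be positive")
        rows.append((ev.I_B, np.log10(ev.t_D_us), ev.i_rms_nA))
    return LabeledFeatureSet(np.asarray(rows, float),
                             np.full(len(rows), code, dtype=int))


def balance_classes(fs: LabeledFeatureSet, seed=0) -> LabeledFeatureSet:
    """Shuffle and downsample every class (without replacement) to the minority count."""
    counts = fs.class_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes to balance")
    if min(counts.values()) == 0:
        raise ValueError("a class has zero rows")
    rng = np.random.default_rng(seed)
    n_min = min(counts.values())
    keep = []
    for c in counts:
        idx = np.flatnonzero(fs.y == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    keep = np.concatenate(keep)
    rng.shuffle(keep)
    return LabeledFeatureSet(fs.X[keep], fs.y[keep], fs.feature_names)


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameters of the Gaussian-kernel SVM protocol."""

    kernel_scale: float = 2.0
    box_constraint: float = 1.0
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.kernel_scale <= 0 or self.box_constraint <= 0:
            raise ValueError("kernel_scale and box_constraint must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    @property
    def gamma(self) -> float:
        # K = exp(-||x-y||^2 / s^2)  <=>  sklearn gamma = 1/s^2
        return 1.0 / self.kernel_scale ** 2


@dataclass
class SVMArtifact:
    """Trained classifier: z-score standardization record + one-vs-one SVC."""

    scaler: StandardScaler
    svc: SVC
    classes: np.ndarray
    feature_names: tuple
    config: SVMConfig
    schema_version: int = SCHEMA_VERSION

    def save(self, path):
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "SVMArtifact":
        with open(path, "rb") as fh:
            art = pickle.load(fh)
        if art.schema_version != SCHEMA_VERSION:
            raise ValueError(f"artifact schema {art.schema_version} != {SCHEMA_VERSION}")
        return art


def train_svm(train: LabeledFeatureSet, cfg: SVMConfig = SVMConfig()) -> SVMArtifact:
    """Fit the one-vs-one Gaussian-kernel SVM on standardized features."""
    counts = train.class_counts()
    if len(counts) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if min(counts.values()) < 5:
        raise ValueError("need at least 5 rows per class")
    scaler = StandardScaler().fit(train.X)
    svc = SVC(
        C=cfg.box_constraint,
        kernel="rbf",
        gamma=cfg.gamma,
        decision_function_shape="ovo",
        random_state=cfg.seed,
    ).fit(scaler.transform(train.X), train.y)
    return SVMArtifact(scaler=scaler, svc=svc, classes=svc.classes_,
                       feature_names=train.feature_names, config=cfg)


def _ovo_class_scores(svc: SVC, Xz: np.ndarray) -> np.ndarray:
    """Per-class summed one-vs-one decision margins (ties broken by margin sum)."""
    dec = svc.decision_function(Xz)
    k = len(svc.classes_)
    if k == 2:
        dec = np.atleast_1d(dec).reshape(-1, 1)
        # sklearn's binary decision function is positive for classes_[1]
        return np.column_stack([-dec[:, 0], dec[:, 0]])
    scores = np.zeros((Xz.shape[0], k))
    col = 0
    for i in range(k):
        for j in range(i + 1, k):
            scores[:, i] += dec[:, col]
            scores[:, j] -= dec[:, col]
            col += 1
    return scores


def predict(artifact: SVMArtifact, events):
    """Predict labels and per-class decision scores for new events.

    ``events`` may be a LabeledFeatureSet, a feature matrix, or a feature
    table with the training schema.  Returns (labels, scores) where scores
    has one column per class in ``artifact.classes`` order.
    """
    if isinstance(events, LabeledFeatureSet):
        X = events.X
        names = events.feature_names
    elif isinstance(events, pd.DataFrame):
        fs = build_features(events)
        X, names = fs.X, fs.feature_names
    else:
        X = np.asarray(events, dtype=float)
        names = artifact.feature_names
    if tuple(names) != tuple(artifact.feature_names) or X.shape[1] != len(artifact.feature_names):
        raise ValueError("feature schema mismatch with the trained artifact")
    Xz = artifact.scaler.transform(X)
    return artifact.svc.predict(Xz), _ovo_class_scores(artifact.svc, Xz)


@dataclass
class EvalReport:
    """Cross-validation report aggregated over out-of-fold predictions."""

    classes: np.ndarray
    confusion: np.ndarray
    accuracy_pct: float
    tpr: dict[int, float]
    fnr: dict[int, float]
    auc: dict[int, float]
    macro_auc: float
    fold_assignments: np.ndarray
    oof_labels: np.ndarray = field(repr=False, default=None)
    oof_scores: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes.tolist(),
            "confusion": self.confusion.tolist(),
            "accuracy_pct": self.accuracy_pct,
            "tpr": {int(k): v for k, v in self.tpr.items()},
            "fnr": {int(k): v for k, v in self.fnr.items()},
            "auc": {int(k): v for k, v in self.auc.items()},
            "macro_auc": self.macro_auc,
        }


def cross_validate(fs: LabeledFeatureSet, cfg: SVMConfig = SVMConfig()) -> EvalReport:
    """Stratified k-fold cross-validation with fold-internal standardization.

    The z-score record is refit on each training fold (no leakage of test
    statistics); the report aggregates out-of-fold predictions into a
    confusion matrix, per-class TPR/FNR and one-vs-rest AUC.
    """
    counts = fs.class_counts()
    if cfg.n_folds > min(counts.values()):
        raise ValueError("n_folds exceeds the minority class count")
    classes = np.array(sorted(counts))
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    n = len(fs)
    oof_pred = np.empty(n, dtype=int)
    oof_scores = np.empty((n, len(classes)))
    folds = np.empty(n, dtype=int)
    for k, (tr, te) in enumerate(skf.split(fs.X, fs.y)):
        art = train_svm(LabeledFeatureSet(fs.X[tr], fs.y[tr], fs.feature_names), cfg)
        labels, scores = predict(art, fs.X[te])
        oof_pred[te] = labels
        oof_scores[te] = scores
        folds[te] = k
    cm = confusion_matrix(fs.y, oof_pred, labels=classes)
    tpr = {int(c): cm[i, i] / cm[i].sum() for i, c in enumerate(classes)}
    auc = {
        int(c): float(roc_auc_score(fs.y == c, oof_scores[:, i]))
        for i, c in enumerate(classes)
    }
    return EvalReport(
        classes=classes,
        confusion=cm,
        accuracy_pct=100.0 * float((oof_pred == fs.y).mean()),
        tpr=tpr,
        fnr={c: 1.0 - v for c, v in tpr.items()},
        auc=auc,
        macro_auc=float(np.mean(list(auc.values()))),
        fold_assignments=folds,
        oof_labels=oof_pred,
        oof_scores=oof_scores,
    )


def roc_auc(fs: LabeledFeatureSet, cfg: SVMConfig = SVMConfig()) -> dict:
    """Per-class one-vs-rest AUC on out-of-fold decision scores (macro under 'macro')."""
    rep = cross_validate(fs, cfg)
    out = dict(rep.auc)
    out["macro"] = rep.macro_auc
    return out


def structural_feature_rate(events, classifier) -> float:
    """Fraction of events flagged as carrying structural features.

    ``classifier`` is either a trained :class:`SVMArtifact` (events assigned
    to the high-i_rms mtDNA class count as structural) or a plain i_rms
    threshold in nA.
    """
    if isinstance(events, LabeledFeatureSet):
        n = len(events)
    else:
        n = len(events)
    if n == 0:
        raise ValueError("no events supplied")
    if isinstance(classifier, SVMArtifact):
        labels, _ = predict(classifier, events)
        return float(np.mean(labels == MTDNA_CODE))
    thresh = float(classifier)
    if isinstance(events, LabeledFeatureSet):
        irms = events.X[:, list(events.feature_names).index("i_rms_nA")]
    elif isinstance(events, pd.DataFrame):
        irms = events["i_rms_nA"].to_numpy(float)
    else:
        irms = np.asarray([ev.i_rms_nA for ev in events], dtype=float)
    return float(np.mean(irms > thresh))
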