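"""Cross-validated K-NN / LDA / RBF-SVM classification of CNP vs control.

All classifiers are evaluated under seeded stratified k-fold cross-validation
(default 5 folds).  Standardization — and, when enabled, the NCA feature
ranking — is fit on the training folds only.  Held-out predictions are pooled
into a single confusion matrix from which accuracy, sensitivity (true
positive rate of the CNP class) and specificity (true negative rate of the
control class) are derived:

    accuracy    = (TP + TN) / total
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from musclenet import nca as _nca
from musclenet.features import parse_feature_name

CLASSIFIERS = ("knn", "svm", "lda")


@dataclass
class CvConfig:
    n_folds: int = 5
    stratified: bool = True
    seed: int = 0
    positive_class: str = "CNP"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def make_classifier(
    name: str,
    knn_k: int = 5,
    svm_c: float = 1.0,
    svm_gamma="auto",
    lda_regularize: bool = False,
):
    """Classifier factory with the study's settings.

    K-NN: Euclidean distance, 5 neighbours (majority vote; ties resolved
    toward the lowest class index).  LDA: shared-covariance linear
    discriminant (``lda_regularize`` switches to the shrinkage-regularised
    lsqr solver for near-singular covariances).  SVM: RBF kernel, C=1,
    gamma = 1/n_features on standardized inputs ("auto").
    """
    name = name.lower()
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=knn_k, metric="euclidean")
    if name == "lda":
        if lda_regularize:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        return LinearDiscriminantAnalysis()
    if name == "svm":
        return SVC(C=svm_c, kernel="rbf", gamma=svm_gamma)
    raise ValueError(f"unknown classifier {name!r}; one of {CLASSIFIERS}")


@dataclass
class ClassificationReport:
    """Pooled confusion matrix and derived rates for one evaluation cell."""

    classifier: str
    task: str
    feature_subset: str
    tp: int
    fn: int
    fp: int
    tn: int
    per_fold: list = field(default_factory=list)
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0
    positive_class: str = "CNP"

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "task": self.task,
            "feature_subset": self.feature_subset,
            "positive_class": self.positive_class,
            "seed": self.seed,
            "confusion": {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_fold": self.per_fold,
            "hyperparams": self.hyperparams,
        }


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive_class: str
) -> tuple[int, int, int, int]:
    """(TP, FN, FP, TN) with the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive_class
    tp = int(np.sum(pos & (y_pred == positive_class)))
    fn = int(np.sum(pos & (y_pred != positive_class)))
    fp = int(np.sum(~pos & (y_pred == positive_class)))
    tn = int(np.sum(~pos & (y_pred != positive_class)))
    return tp, fn, fp, tn


def fold_indices(table: pd.DataFrame, cfg: CvConfig) -> list:
    """Seeded (stratified) fold split, a pure function of (seed, row ids).

    Rows are put in canonical (sorted-id) order before splitting, so fold
    membership does not depend on the order the table was assembled in.
    """
    pos = np.argsort(np.asarray(table.index.astype(str)), kind="stable")
    y = table["group"].to_numpy()[pos]
    if cfg.stratified:
        splitter = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
        )
    else:
        splitter = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    folds = []
    for tr, te in splitter.split(np.zeros(len(y)), y):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold does not contain both classes")
        folds.append((pos[tr], pos[te]))
    return folds


def cross_validate(
    table: pd.DataFrame,
    classifier_name: str,
    cv_cfg: CvConfig | None = None,
    feature_subset: list[str] | None = None,
    nca_k: int | None = None,
    nca_params: dict | None = None,
    task: str = "",
    subset_id: str | None = None,
    **clf_kwargs,
) -> ClassificationReport:
    """Stratified CV with in-fold standardization and optional in-fold NCA.

    ``feature_subset`` restricts the columns up front; ``nca_k`` additionally
    fits the NCA ranking on each training fold and keeps its top-k features.
    """
    cv_cfg = cv_cfg or CvConfig()
    nca_params = nca_params or {}
    cols = _nca.feature_columns(table)
    if feature_subset is not None:
        missing = [c for c in feature_subset if c not in cols]
        if missing:
            raise ValueError(f"unknown feature columns: {missing}")
        cols = list(feature_subset)
    if table["group"].nunique() < 2:
        raise ValueError("both classes must be present")
    y_all = table["group"].to_numpy()
    tp = fn = fp = tn = 0
    per_fold = []
    for fold_no, (tr_idx, te_idx) in enumerate(fold_indices(table, cv_cfg), 1):
        train = table.iloc[tr_idx]
        test = table.iloc[te_idx]
        std_train, scaler = _nca.standardize(train[["group", *cols]])
        std_test = _nca.apply_scaler(test[["group", *cols]], scaler)
        use_cols = _nca.feature_columns(std_train)
        if nca_k is not None:
            sel = _nca.nca_fit(
                std_train[use_cols].to_numpy(),
                train["group"].to_numpy(),
                seed=cv_cfg.seed,
                **nca_params,
            )
            k = min(nca_k, len(use_cols))
            use_cols = [use_cols[i] for i in sel.ranking_[:k]]
        clf = make_classifier(classifier_name, **clf_kwargs)
        if classifier_name == "knn" and len(train) < clf.n_neighbors:
            raise ValueError("training fold smaller than the number of neighbours")
        clf.fit(std_train[use_cols].to_numpy(), train["group"].to_numpy())
        pred = clf.predict(std_test[use_cols].to_numpy())
        ftp, ffn, ffp, ftn = confusion_from_predictions(
            test["group"].to_numpy(), pred, cv_cfg.positive_class
        )
        tp, fn, fp, tn = tp + ftp, fn + ffn, fp + ffp, tn + ftn
        per_fold.append(
            {
                "fold": fold_no,
                "n_test": int(len(te_idx)),
                "accuracy": float(np.mean(pred == test["group"].to_numpy())),
            }
        )
    return ClassificationReport(
        classifier=classifier_name,
        task=task,
        feature_subset=subset_id or ("nca" if nca_k is not None else "all"),
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        per_fold=per_fold,
        hyperparams={
            "nca_k": nca_k,
            "n_folds": cv_cfg.n_folds,
            "stratified": cv_cfg.stratified,
            **clf_kwargs,
        },
        seed=cv_cfg.seed,
        positive_class=cv_cfg.positive_class,
    )


def per_muscle_evaluation(
    table: pd.DataFrame,
    classifier_name: str,
    cv_cfg: CvConfig | None = None,
    task: str = "",
    **kwargs,
) -> dict[str, ClassificationReport]:
    """One report per muscle using only that muscle's features (both sides).

    Coherence features are included for every muscle that takes part in the
    pair.
    """
    reports = {}
    cols = _nca.feature_columns(table)
    muscles = sorted(
        {m for c in cols for m in parse_feature_name(c)["muscles"]}
    )
    for muscle in muscles:
        subset = [
            c for c in cols if muscle in parse_feature_name(c)["muscles"]
        ]
        reports[muscle] = cross_validate(
            table,
            classifier_name,
            cv_cfg,
            feature_subset=subset,
            task=task,
            subset_id=f"muscle:{muscle}",
            **kwargs,
        )
    return reports


def task_comparison(
    tables: dict[str, pd.DataFrame],
    cv_cfg: CvConfig | None = None,
    nca_k: int = 16,
    nca_params: dict | None = None,
    classifiers: tuple[str, ...] = CLASSIFIERS,
) -> dict[tuple[str, str, str], ClassificationReport]:
    """The full results grid: tasks x classifiers x {all, NCA-selected}.

    ``tables`` maps "rectilinear" and "curvilinear" to per-task feature
    tables; the pooled "combine" view is built automatically if absent.
    """
    from musclenet.features import combine_tasks

    tables = dict(tables)
    if "combine" not in tables:
        tables["combine"] = combine_tasks(
            {t: tables[t] for t in ("rectilinear", "curvilinear")}
        )
    reports = {}
    for task in ("curvilinear", "rectilinear", "combine"):
        df = tables[task]
        for clf in classifiers:
            reports[(task, clf, "all")] = cross_validate(
                df, clf, cv_cfg, task=task, subset_id="all"
            )
            reports[(task, clf, "nca")] = cross_validate(
                df,
                clf,
                cv_cfg,
                nca_k=nca_k,
                nca_params=nca_params,
                task=task,
                subset_id="nca",
            )
    return reports


def summary_table(
    reports: dict[tuple[str, str, str], ClassificationReport]
) -> pd.DataFrame:
    """Flat summary: one row per (feature set, classifier, metric), task columns."""
    tasks = ("curvilinear", "rectilinear", "combine")
    rows = []
    for subset in ("all", "nca"):
        for clf in CLASSIFIERS:
            for metric in ("accuracy", "specificity", "sensitivity"):
                row = {"feature_set": subset, "classifier": clf, "metric": metric}
                for task in tasks:
                    rep = reports.get((task, clf, subset))
                    row[task] = (
                        round(100.0 * getattr(rep, metric), 2) if rep else np.nan
                    )
                rows.append(row)
    return pd.DataFrame(rows)
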