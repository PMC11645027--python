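"""Imbalance-aware staging classifiers.

The stack mirrors a standard clinical-ML recipe on the 144-feature table:
SMOTE oversampling to equalise class counts, a stratified 80/20 split,
z-score normalisation fitted on the training set, dimensionality
reduction (PCA to a retained-variance target, or SelectKBest with mutual
information), then grid-searched classifiers — linear and RBF SVM, KNN,
decision tree, random forest, gradient boosting, logistic regression —
and a funnel multilayer perceptron (512-256-128-64-32 ReLU layers with a
softmax output, L2 regularisation, Adam, early stopping).

Two orderings are supported. The default is leak-free: the split happens
first and SMOTE / scaler / PCA / MI see training rows only. With
``paper_order=True`` SMOTE is applied to the full table before the split
and PCA is fitted on the full standardized matrix, reproducing the
literal published recipe for comparison (z-scoring stays train-fitted in
both modes, as it is explicitly an anti-leakage step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import partial

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import SelectKBest, mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, DomainError


@dataclass
class CohortTable:
    """A feature matrix with class labels and participant ids."""

    features: np.ndarray
    labels: np.ndarray
    ids: list[str]
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.features) != len(self.labels) or len(self.features) != len(self.ids):
            raise DomainError("features, labels and ids must have equal row counts")
        if not np.all(np.isfinite(self.features)):
            raise DomainError("feature matrix contains non-finite entries")

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    @classmethod
    def from_frame(cls, frame, label_column: str = "group") -> "CohortTable":
        """Build from a feature table DataFrame (metadata columns excluded)."""
        meta = {"participant_id", label_column, "glfs", "sex", "age"}
        cols = [
            c for c in frame.columns
            if c not in meta and not str(c).startswith("cv_")
        ]
        return cls(
            features=frame[cols].to_numpy(dtype=float),
            labels=frame[label_column].to_numpy(),
            ids=frame["participant_id"].astype(str).tolist()
            if "participant_id" in frame
            else [str(i) for i in range(len(frame))],
            feature_names=cols,
        )


@dataclass(frozen=True)
class PipelineConfig:
    test_fraction: float = 0.2
    split_seed: int = 42
    smote_enabled: bool = True
    smote_k: int = 5
    paper_order: bool = False
    pca_variance: float | int | None = 0.95
    select_k: int | None = None
    metric_average: str = "weighted"

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ConfigError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if self.metric_average not in ("macro", "weighted"):
            raise ConfigError("metric_average must be 'macro' or 'weighted'")


@dataclass(frozen=True)
class MlpSpec:
    """Funnel MLP: each hidden layer halves the previous width."""

    hidden_layers: tuple[int, ...] = (512, 256, 128, 64, 32)
    l2: float = 0.001
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 64
    early_stopping: bool = True
    patience: int = 20
    validation_fraction: float = 0.1


@dataclass
class EvaluationReport:
    model_name: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    classes: list[str]
    best_hyperparameters: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "model": self.model_name,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "classes": self.classes,
            "confusion_matrix": self.confusion.tolist(),
            "best_hyperparameters": {
                k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v))
                for k, v in self.best_hyperparameters.items()
            },
        }


def smote_balance(table: CohortTable, k: int = 5, seed: int = 0) -> CohortTable:
    """Equalise class counts by synthetic minority oversampling.

    Every class is raised to the majority class's count. Each synthetic
    row is a convex combination ``x + u * (x_nn - x)`` with ``u ~ U(0,1)``
    of a minority sample and one of its k nearest same-class neighbours
    (Euclidean distance). Original rows are preserved verbatim; the
    result is deterministic under a fixed seed.
    """
    counts = table.class_counts()
    majority = max(counts.values())
    for label, count in counts.items():
        if count < majority and count <= k:
            raise ConfigError(
                f"class {label!r} has {count} rows but SMOTE needs more than k={k} "
                f"neighbours; use a smaller k"
            )
    if all(c == majority for c in counts.values()):
        return table
    rng = np.random.default_rng(seed)
    X_parts = [table.features]
    y_parts = [table.labels]
    id_parts = list(table.ids)
    for label in sorted(counts):  # stable class order for determinism
        deficit = majority - counts[label]
        if deficit == 0:
            continue
        mask = table.labels == label
        X_cls = table.features[mask]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_cls)
        _, neighbours = nn.kneighbors(X_cls)  # column 0 is the point itself
        base = rng.integers(0, len(X_cls), size=deficit)
        pick = rng.integers(1, k + 1, size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)
        partners = neighbours[base, pick]
        synthetic = X_cls[base] + u[:, None] * (X_cls[partners] - X_cls[base])
        X_parts.append(synthetic)
        y_parts.append(np.full(deficit, label, dtype=table.labels.dtype))
        id_parts.extend(f"smote_{label}_{i:03d}" for i in range(deficit))
    return CohortTable(
        features=np.vstack(X_parts),
        labels=np.concatenate(y_parts),
        ids=id_parts,
        feature_names=table.feature_names,
    )


def split(table: CohortTable, config: PipelineConfig | None = None) -> tuple[CohortTable, CohortTable]:
    """Stratified train/test split (default 20% test, random state 42)."""
    if config is None:
        config = PipelineConfig()
    counts = table.class_counts()
    if min(counts.values()) < 2:
        raise ConfigError(f"every class needs >= 2 rows to stratify; got {counts}")
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=config.test_fraction,
        random_state=config.split_seed,
        stratify=table.labels,
    )

    def subset(indices: np.ndarray) -> CohortTable:
        return CohortTable(
            features=table.features[indices],
            labels=table.labels[indices],
            ids=[table.ids[i] for i in indices],
            feature_names=table.feature_names,
        )

    return subset(train_idx), subset(test_idx)


def zscore(train: CohortTable, test: CohortTable) -> tuple[CohortTable, CohortTable, StandardScaler]:
    """Standardize features with train-set statistics only.

    Constant training columns are dropped (with a warning) from both
    splits before fitting; an all-constant matrix is an error.
    """
    std = train.features.std(axis=0, ddof=0)
    keep = std > 0
    if not keep.any():
        raise DomainError("all feature columns are constant on the training set")
    if not keep.all():
        dropped = (
            [n for n, k in zip(train.feature_names, keep) if not k]
            if train.feature_names
            else int((~keep).sum())
        )
        warnings.warn(f"dropping constant training columns: {dropped}", stacklevel=2)
    names = [n for n, k in zip(train.feature_names, keep) if k] if train.feature_names else None
    scaler = StandardScaler().fit(train.features[:, keep])

    def transform(t: CohortTable) -> CohortTable:
        return CohortTable(scaler.transform(t.features[:, keep]), t.labels, t.ids, names)

    return transform(train), transform(test), scaler


def pca_reduce(
    train: CohortTable,
    test: CohortTable,
    pca_variance: float | int = 0.95,
    full: CohortTable | None = None,
) -> tuple[CohortTable, CohortTable, PCA]:
    """Project both splits onto principal components.

    ``pca_variance`` in (0, 1) retains the smallest number of components
    whose cumulative explained variance reaches it; an integer fixes the
    component count. By default components are fitted on the training
    split; passing ``full`` fits them on that matrix instead (the
    published whole-dataset ordering).
    """
    if isinstance(pca_variance, float) and not 0 < pca_variance <= 1:
        raise ConfigError(f"pca_variance must be in (0, 1], got {pca_variance}")
    if isinstance(pca_variance, int) and pca_variance < 1:
        raise ConfigError(f"component count must be >= 1, got {pca_variance}")
    fit_on = full.features if full is not None else train.features
    n_components = pca_variance
    if isinstance(pca_variance, float) and pca_variance == 1.0:
        n_components = min(fit_on.shape[0] - 1, fit_on.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full").fit(fit_on)
    names = [f"PC{i + 1}" for i in range(pca.n_components_)]

    def transform(t: CohortTable) -> CohortTable:
        return CohortTable(pca.transform(t.features), t.labels, t.ids, names)

    return transform(train), transform(test), pca


def select_k_best_mi(
    train: CohortTable, test: CohortTable, k: int, seed: int = 0
) -> tuple[CohortTable, CohortTable, np.ndarray]:
    """Keep the k features most informative about the stage label.

    Mutual information is estimated on the training split only; the
    returned score vector (one entry per input feature) exposes the
    importance ranking.
    """
    p = train.features.shape[1]
    if not 1 <= k <= p:
        raise ConfigError(f"k must be in [1, {p}], got {k}")
    selector = SelectKBest(
        score_func=partial(mutual_info_classif, random_state=seed), k=k
    ).fit(train.features, train.labels)
    scores = selector.scores_
    mask = selector.get_support()
    names = (
        [n for n, m in zip(train.feature_names, mask) if m] if train.feature_names else None
    )

    def transform(t: CohortTable) -> CohortTable:
        return CohortTable(t.features[:, mask], t.labels, t.ids, names)

    return transform(train), transform(test), scores


def _model_factories(seed: int) -> dict:
    return {
        "SVM-lin": lambda: SVC(kernel="linear", random_state=seed),
        "SVM-rbf": lambda: SVC(kernel="rbf", random_state=seed),
        "KNN": KNeighborsClassifier,
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        "RF": lambda: RandomForestClassifier(random_state=seed),
        "GB": lambda: GradientBoostingClassifier(random_state=seed),
        "LR": lambda: LogisticRegression(solver="liblinear", max_iter=2000, random_state=seed),
    }


#: Full hyperparameter grids searched for each traditional model family.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVM-lin": {"C": [0.1, 1, 10, 100, 1000, 10000]},
    "SVM-rbf": {
        "C": [0.1, 1, 10, 100, 1000, 10000],
        "gamma": [0.001, 0.01, 0.1, 1, 10],
    },
    "KNN": {"n_neighbors": list(range(1, 51)), "weights": ["uniform", "distance"]},
    "DT": {"max_depth": list(range(1, 51)), "criterion": ["gini", "entropy"]},
    "RF": {
        "n_estimators": [50, 100, 200, 400, 600, 800, 1000, 1200],
        "max_depth": [None, 5, 10, 20, 30, 50],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 2, 4],
        "bootstrap": [True, False],
    },
    "GB": {
        "n_estimators": [50, 100, 200, 400, 600, 800, 1000, 1200],
        "learning_rate": [0.1, 0.01, 0.001],
        "max_depth": [None, 5, 10, 20, 30, 50],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 2, 4],
    },
    "LR": {"C": [0.1, 1, 10], "penalty": ["l1", "l2"]},
}

#: Reduced grids for routine runs; the full grids stay available above.
SMALL_GRIDS: dict[str, dict[str, list]] = {
    "SVM-lin": {"C": [0.1, 1, 10, 100]},
    "SVM-rbf": {"C": [1, 10, 100], "gamma": [0.001, 0.01, 0.1]},
    "KNN": {"n_neighbors": [1, 3, 5, 9, 15], "weights": ["uniform", "distance"]},
    "DT": {"max_depth": [3, 6, 12, 24], "criterion": ["gini", "entropy"]},
    "RF": {"n_estimators": [50, 200], "max_depth": [None, 10]},
    "GB": {"n_estimators": [50, 200], "learning_rate": [0.1, 0.01], "max_depth": [3, 5]},
    "LR": {"C": [0.1, 1, 10], "penalty": ["l1", "l2"]},
}


def grid_search_train(
    train: CohortTable,
    model_family: str,
    grid: dict[str, list] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
):
    """Exhaustive cross-validated grid search for one model family.

    Selects by CV accuracy, breaking ties by first-in-grid order, then
    refits the winner on the full training split. Returns the fitted
    estimator and its winning hyperparameters.
    """
    factories = _model_factories(seed)
    if model_family not in factories:
        raise ConfigError(f"unknown model family {model_family!r}; expected {list(factories)}")
    if grid is None:
        grid = DEFAULT_GRIDS[model_family]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigError("hyperparameter grid must be non-empty")
    # stratified CV cannot have more folds than the smallest class
    smallest = min(np.unique(train.labels, return_counts=True)[1])
    cv_folds = max(2, min(cv_folds, int(smallest)))
    search = GridSearchCV(
        factories[model_family](),
        param_grid=grid,
        scoring="accuracy",
        cv=cv_folds,
        n_jobs=1,
        refit=True,
    )
    search.fit(train.features, train.labels)
    return search.best_estimator_, dict(search.best_params_)


def mlp_train(train: CohortTable, spec: MlpSpec | None = None, seed: int = 0) -> MLPClassifier:
    """Fit the funnel MLP on a training split.

    Multiclass targets are handled with a softmax output over one-hot
    coded classes inside the estimator; ``spec.l2`` maps to the L2
    penalty, ``spec.epochs`` to the iteration cap, and early stopping
    monitors a held-out fraction of the training rows.
    """
    if spec is None:
        spec = MlpSpec()
    model = MLPClassifier(
        hidden_layer_sizes=spec.hidden_layers,
        activation="relu",
        solver="adam",
        alpha=spec.l2,
        learning_rate_init=spec.learning_rate,
        max_iter=spec.epochs,
        batch_size=min(spec.batch_size, len(train)),
        early_stopping=spec.early_stopping,
        n_iter_no_change=spec.patience,
        validation_fraction=spec.validation_fraction,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        model.fit(train.features, train.labels)
    if not np.all(np.isfinite(model.loss_curve_)):
        raise DomainError("MLP training diverged to a non-finite loss")
    return model


def evaluate(model, test: CohortTable, metric_average: str = "weighted") -> EvaluationReport:
    """Accuracy, averaged precision/recall/F1 and the confusion matrix.

    Confusion-matrix rows are true classes, columns predictions. Classes
    absent from the test split contribute zero-division-guarded zeros to
    the averaged metrics.
    """
    if len(test) == 0:
        raise DomainError("cannot evaluate on an empty test set")
    predictions = model.predict(test.features)
    classes = sorted(set(np.asarray(test.labels).tolist()) | set(np.asarray(predictions).tolist()))
    precision, recall, f1, _ = precision_recall_fscore_support(
        test.labels, predictions, labels=classes, average=metric_average, zero_division=0
    )
    return EvaluationReport(
        model_name=type(model).__name__,
        accuracy=float(accuracy_score(test.labels, predictions)),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        confusion=confusion_matrix(test.labels, predictions, labels=classes),
        classes=list(classes),
    )


def run_classification(
    table: CohortTable,
    config: PipelineConfig | None = None,
    models: list[str] | None = None,
    grids: dict[str, dict] | None = None,
    mlp_spec: MlpSpec | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> dict[str, EvaluationReport]:
    """Full classification experiment on a cohort feature table.

    Runs the configured transform chain, then each requested model family
    (grid-searched) plus the funnel MLP (``"MLP"``), each evaluated on the
    held-out split. With ``pca_variance`` set the MLP variant is the
    PCA-enhanced one (``"MLP+PCA"``).
    """
    if config is None:
        config = PipelineConfig()
    if models is None:
        models = ["SVM-rbf", "KNN", "RF", "LR", "MLP"]
    if grids is None:
        grids = SMALL_GRIDS

    working = table
    if config.paper_order and config.smote_enabled:
        working = smote_balance(working, k=config.smote_k, seed=seed)
    train, test = split(working, config)
    if not config.paper_order and config.smote_enabled:
        train = smote_balance(train, k=config.smote_k, seed=seed)
    train, test, _ = zscore(train, test)
    full_std = None
    if config.paper_order:
        full_std = CohortTable(
            np.vstack([train.features, test.features]),
            np.concatenate([train.labels, test.labels]),
            train.ids + test.ids,
            train.feature_names,
        )
    if config.select_k is not None:
        train, test, _ = select_k_best_mi(train, test, config.select_k, seed=seed)
    elif config.pca_variance is not None:
        train, test, _ = pca_reduce(train, test, config.pca_variance, full=full_std)

    reports: dict[str, EvaluationReport] = {}
    for family in models:
        if family == "MLP":
            model = mlp_train(train, mlp_spec, seed=seed)
            best: dict = {"spec": str(mlp_spec or MlpSpec())}
            name = "MLP+PCA" if config.pca_variance is not None and config.select_k is None else "MLP"
        else:
            model, best = grid_search_train(train, family, grids.get(family), cv_folds, seed=seed)
            name = family
        report = evaluate(model, test, config.metric_average)
        report.model_name = name
        report.best_hyperparameters = best
        reports[name] = report
    return reports
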