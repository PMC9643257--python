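"""Dataset assembly, stratified splitting and class-weighted SVM training.

The classifier follows the study protocol: a 50/50 stratified random split,
a grid search over kernel family (sigmoid, RBF, polynomial), kernel
parameters and the regularisation parameter C under five-fold stratified
cross-validation on the training half, with per-class C weighted inversely
to class frequency ("balanced" mode) to counter the heavy normal:aspirating
imbalance. Feature standardisation is deliberately not applied: SSCs are
frequency locations whose scale and ordering are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from sscswallow.audio_io import ValidationError
from sscswallow.dsp import FeatureVector, feature_names


@dataclass
class Dataset:
    """Feature matrix with labels and clip identifiers."""

    features: np.ndarray   # (n, d)
    labels: np.ndarray     # (n,) in {0, 1}
    clip_ids: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.features) == len(self.labels) == len(self.clip_ids)):
            raise ValidationError("features, labels and clip_ids disagree in length")
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        if len(self.labels) and not np.isin(self.labels, [0, 1]).all():
            raise ValidationError("labels must be 0 (normal) or 1 (aspirating)")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_feature_vectors(cls, vectors: Sequence[FeatureVector]) -> "Dataset":
        if not vectors:
            raise ValidationError("no clips: cannot build an empty dataset")
        return cls(features=np.stack([v.values for v in vectors]),
                   labels=np.array([v.label for v in vectors]),
                   clip_ids=[v.clip_id for v in vectors])

    def to_frame(self) -> pd.DataFrame:
        names = feature_names(self.features.shape[1] // 2)
        df = pd.DataFrame(self.features, columns=names)
        df.insert(0, "clip_id", self.clip_ids)
        df.insert(1, "label", self.labels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        cols = [c for c in df.columns if c.startswith("ssc_")]
        if not cols or "label" not in df.columns:
            raise ValidationError("feature table must have 'label' and ssc_* columns")
        ids = df["clip_id"].astype(str).tolist() if "clip_id" in df else \
            [str(i) for i in range(len(df))]
        return cls(features=df[cols].to_numpy(float),
                   labels=df["label"].to_numpy(int), clip_ids=ids)


@dataclass
class SplitResult:
    train: Dataset
    test: Dataset
    seed: int


@dataclass(frozen=True)
class SvmConfig:
    """One grid point: kernel family and its parameters.

    ``class_weighting='balanced'`` scales each class's C by n / (2 n_c),
    i.e. inversely to class frequency.
    """

    kernel: str = "poly"
    C: float = 1.0
    gamma: float | str = "scale"
    degree: int = 2
    class_weighting: str = "balanced"

    def to_svc(self) -> SVC:
        if self.kernel not in ("sigmoid", "rbf", "poly"):
            raise ValidationError(f"unsupported kernel {self.kernel!r}")
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                   degree=self.degree if self.kernel == "poly" else 3,
                   class_weight="balanced" if self.class_weighting == "balanced" else None)


#: Default search grid. Spans the kernel families searched in the study and
#: brackets its reported optimum (polynomial kernel, degree 2, C = 1).
DEFAULT_GRID: list[SvmConfig] = [
    SvmConfig(kernel=k, C=C, gamma=g, degree=d)
    for k in ("sigmoid", "rbf", "poly")
    for C in (0.1, 1.0, 10.0, 100.0)
    for g in ("scale", 0.001, 0.01, 0.1)
    for d in ((2, 3) if k == "poly" else (3,))
]

#: The study's reported optimum as a single-point grid.
PAPER_OPTIMUM_GRID: list[SvmConfig] = [
    SvmConfig(kernel="poly", C=1.0, gamma="scale", degree=2)
]


@dataclass
class TrainedModel:
    """Fitted SVM plus the metadata needed to reproduce it."""

    config: SvmConfig
    estimator: SVC
    cv_seed: int
    n_features: int
    fold_scores: np.ndarray = field(default_factory=lambda: np.array([]))
    grid_table: pd.DataFrame | None = None
    class_weights: dict[int, float] = field(default_factory=dict)


def balanced_class_weights(labels: np.ndarray) -> dict[int, float]:
    """Inverse-frequency weights, w_c = n / (n_classes * n_c)."""
    labels = np.asarray(labels)
    n = len(labels)
    classes = np.unique(labels)
    return {int(c): n / (len(classes) * int((labels == c).sum())) for c in classes}


def stratified_split(ds: Dataset, fraction: float = 0.5, seed: int = 0) -> SplitResult:
    """Per-class shuffled partition into test (``fraction``) and train sides.

    Each class c contributes ``round(fraction * n_c)`` items to the test
    side, so with an odd class count the extra item stays in training. The
    shuffle is a per-class permutation under the given seed.
    """
    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for c in np.unique(ds.labels):
        members = np.flatnonzero(ds.labels == c)
        if len(members) < 2:
            raise ValidationError(f"class {c} has fewer than 2 members; cannot split")
        perm = rng.permutation(members)
        # half-down rounding: on a .5 tie (odd class count at fraction 0.5)
        # the extra item stays on the training side
        n_test = int(np.ceil(fraction * len(members) - 0.5))
        n_test = min(max(n_test, 1), len(members) - 1)
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    train_idx.sort()
    test_idx.sort()

    def take(idx: list[int]) -> Dataset:
        return Dataset(features=ds.features[idx], labels=ds.labels[idx],
                       clip_ids=[ds.clip_ids[i] for i in idx])

    return SplitResult(train=take(train_idx), test=take(test_idx), seed=seed)


def _param_grid(grid: Sequence[SvmConfig]) -> list[dict]:
    return [{"kernel": [c.kernel], "C": [c.C], "gamma": [c.gamma],
             "degree": [c.degree if c.kernel == "poly" else 3],
             "class_weight": ["balanced" if c.class_weighting == "balanced" else None]}
            for c in grid]


def grid_search_train(train: Dataset, grid: Sequence[SvmConfig] | None = None,
                      folds: int = 5, cv_seed: int = 0,
                      scoring: str = "accuracy") -> TrainedModel:
    """Grid-searched, cross-validated SVM fit on the training set.

    Selects the grid point with the highest mean stratified k-fold
    validation score (ties broken by grid order) and refits it on the full
    training set. Fold assignment is shuffled under ``cv_seed`` and the full
    per-grid-point score table is kept in the returned metadata.
    """
    if grid is None:
        grid = DEFAULT_GRID
    if len(grid) == 0:
        raise ValidationError("empty parameter grid")
    if folds < 2:
        raise ValidationError("need at least 2 cross-validation folds")
    counts = np.bincount(train.labels, minlength=2)
    if counts.min() < folds:
        raise ValidationError(
            f"minority class has {counts.min()} members < {folds} folds")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv_seed)
    search = GridSearchCV(SVC(), _param_grid(grid), scoring=scoring, cv=cv,
                          refit=True, n_jobs=1)
    search.fit(train.features, train.labels)
    best = search.best_params_
    config = SvmConfig(kernel=best["kernel"], C=best["C"], gamma=best["gamma"],
                       degree=best["degree"],
                       class_weighting="balanced" if best["class_weight"] else "none")
    res = search.cv_results_
    i = search.best_index_
    fold_scores = np.array([res[f"split{k}_test_score"][i] for k in range(folds)])
    table = pd.DataFrame({
        "kernel": res["param_kernel"], "C": res["param_C"],
        "gamma": res["param_gamma"], "degree": res["param_degree"],
        "mean_score": res["mean_test_score"], "rank": res["rank_test_score"],
    })
    weights = (balanced_class_weights(train.labels)
               if config.class_weighting == "balanced" else {0: 1.0, 1: 1.0})
    return TrainedModel(config=config, estimator=search.best_estimator_,
                        cv_seed=cv_seed, n_features=train.features.shape[1],
                        fold_scores=fold_scores, grid_table=table,
                        class_weights=weights)


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Hard 0/1 labels for a feature matrix; deterministic for a fixed model."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature dimension mismatch: model expects {model.n_features}, "
            f"got {X.shape[1]}")
    return model.estimator.predict(X).astype(int)


def save_model(model: TrainedModel, path: str) -> None:
    """Persist config, seeds, grid metadata and the fitted estimator."""
    joblib.dump({"config": model.config, "estimator": model.estimator,
                 "cv_seed": model.cv_seed, "n_features": model.n_features,
                 "fold_scores": model.fold_scores, "grid_table": model.grid_table,
                 "class_weights": model.class_weights}, path)


def load_model(path: str) -> TrainedModel:
    d = joblib.load(path)
    return TrainedModel(**d)
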