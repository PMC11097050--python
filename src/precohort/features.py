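"""Turning decision points into a numeric feature matrix.

Pipeline order: engineered features and one-hot treatment encodings ->
completeness filter (keep features >= 80 % nonmissing) -> k-nearest-neighbor
imputation (k = 2, uniform weights) -> stratified train/score split ->
standardization (fit on train) -> LASSO stability selection (200
L1-regularized logistic models on 75 % row subsamples; features with a
nonzero coefficient in at least 150 models are stable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .decision_points import DecisionPoint, FLAG_NAMES, dps_to_frame

DEFAULT_ALPHA_GRID = (100, 20, 10, 2, 1.67, 1.43, 1.25, 1.11, 1)

COUNT_COLUMNS = ("n_prescriptions", "n_measurements", "n_consultations", "n_comorbidities")


class EmptyInputError(ValueError):
    """No decision points to build features from."""


class DegenerateInputError(ValueError):
    """The completeness filter removed every feature column."""


class ImputationError(ValueError):
    """A row has no observed feature values at all."""


class StratificationError(ValueError):
    """An outcome class is too small to stratify the split."""


@dataclass
class FeatureMatrix:
    """DP-by-feature numeric matrix with outcome labels and provenance.

    ``X`` holds numeric values with NaN marking missing cells; ``y`` is the
    binary outcome (1 = controlled); ``provenance`` maps each column to one
    of {"baseline", "flag", "engineered", "active_onehot", "new_onehot"}.
    """

    X: pd.DataFrame
    y: pd.Series
    provenance: dict[str, str]
    scaler: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def mask(self) -> pd.DataFrame:
        return self.X.isna()

    def columns_of_kind(self, *kinds: str) -> list[str]:
        return [c for c, k in self.provenance.items() if k in kinds and c in self.X.columns]


def build_features(dps: list[DecisionPoint] | pd.DataFrame) -> FeatureMatrix:
    """Assemble the feature matrix from extracted decision points."""
    frame = dps if isinstance(dps, pd.DataFrame) else dps_to_frame(dps)
    if not len(frame):
        raise EmptyInputError("no decision points supplied")
    frame = frame.reset_index(drop=True)

    provenance: dict[str, str] = {}
    cols: dict[str, pd.Series] = {}

    cols["index_value"] = frame["index_value"].astype(float)
    provenance["index_value"] = "baseline"
    for col in frame.columns:
        if col.startswith("baseline_"):
            cols[col] = frame[col].astype(float)
            provenance[col] = "baseline"
    for name in FLAG_NAMES:
        cols[name] = frame[name].astype(float)
        provenance[name] = "flag"
    cols["has_chronic_comorbidity"] = frame["has_chronic_comorbidity"].astype(float)
    provenance["has_chronic_comorbidity"] = "engineered"
    for name in COUNT_COLUMNS:
        cols[name] = frame[name].astype(float)
        provenance[name] = "engineered"
    for kind, source in (("active_onehot", "active_treatment"), ("new_onehot", "new_treatment")):
        dummies = pd.get_dummies(frame[source], prefix=source.split("_")[0], prefix_sep="=")
        for col in dummies.columns:
            cols[col] = dummies[col].astype(float)
            provenance[col] = kind

    X = pd.DataFrame(cols)
    y = (frame["outcome"] == "controlled").astype(int)
    y.name = "controlled"
    return FeatureMatrix(X=X, y=y, provenance=provenance)


def filter_missing(
    matrix: FeatureMatrix, min_nonmissing: float = 0.8
) -> tuple[FeatureMatrix, list[str]]:
    """Drop features observed in fewer than ``min_nonmissing`` of the rows."""
    frac = 1.0 - matrix.X.isna().mean(axis=0)
    keep = frac[frac >= min_nonmissing].index.tolist()
    dropped = [c for c in matrix.X.columns if c not in keep]
    if not keep:
        raise DegenerateInputError("completeness filter removed every feature")
    return replace(matrix, X=matrix.X[keep].copy()), dropped


def impute_knn(matrix: FeatureMatrix, k: int = 2) -> FeatureMatrix:
    """Fill missing cells with the unweighted mean over the k nearest rows."""
    if matrix.X.isna().all(axis=1).any():
        raise ImputationError("a row has all features missing")
    if not matrix.X.isna().any().any():
        return replace(matrix, X=matrix.X.copy())
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(matrix.X.to_numpy(float))
    X = pd.DataFrame(filled, columns=matrix.X.columns, index=matrix.X.index)
    return replace(matrix, X=X)


def split_train_score(
    matrix: FeatureMatrix, train_frac: float = 0.30, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Outcome-stratified split into a training set and a scoring set.

    |train| = floor(train_frac * n); class proportions in both parts match
    the overall proportion to within one DP.
    """
    counts = matrix.y.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise StratificationError("each outcome class needs at least 2 members")
    idx_train, idx_score = train_test_split(
        matrix.X.index.to_numpy(),
        train_size=train_frac,
        stratify=matrix.y.to_numpy(),
        random_state=seed,
    )
    idx_train.sort()
    idx_score.sort()

    def take(idx):
        return replace(matrix, X=matrix.X.loc[idx].copy(), y=matrix.y.loc[idx].copy())

    return take(idx_train), take(idx_score)


def fit_scaler(matrix: FeatureMatrix) -> dict[str, tuple[float, float]]:
    """Mean/SD per continuous column (baseline + engineered counts)."""
    params: dict[str, tuple[float, float]] = {}
    for col in matrix.columns_of_kind("baseline", "engineered"):
        values = matrix.X[col].to_numpy(float)
        mean = float(np.nanmean(values))
        sd = float(np.nanstd(values))
        params[col] = (mean, sd if sd > 0 else 1.0)
    return params


def apply_scaler(matrix: FeatureMatrix, params: dict[str, tuple[float, float]]) -> FeatureMatrix:
    X = matrix.X.copy()
    for col, (mean, sd) in params.items():
        if col in X.columns:
            X[col] = (X[col] - mean) / sd
    return replace(matrix, X=X, scaler=dict(params))


@dataclass
class StabilityResult:
    alpha: float
    f1_at_alpha: float
    selection_counts: dict[str, int]
    stable_features: list[str]
    n_models: int = 200
    fallback: bool = False


def _lasso(alpha: float, n_samples: int, seed: int) -> LogisticRegression:
    # The grid values are inverse penalties on the mean-log-loss scale
    # (penalty weight lambda = 1/alpha, the glmnet/Lasso convention); they
    # convert to scikit-learn's sum-loss C as alpha / n_samples.
    return LogisticRegression(
        l1_ratio=1.0,
        C=float(alpha) / n_samples,
        solver="liblinear",
        max_iter=500,
        random_state=seed,
    )


def stability_select(
    train: FeatureMatrix,
    alphas: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    n_models: int = 200,
    subsample: float = 0.75,
    min_count: int = 150,
    seed: int = 0,
) -> StabilityResult:
    """LASSO stability selection of outcome-salient features.

    The grid value with the best cross-validated F1 (positive class =
    controlled, 0.5 probability threshold) is chosen; 200 L1-penalized
    logistic models are then fit on independent 75 % row subsamples and a
    feature is stable if its coefficient is nonzero in >= ``min_count`` runs.
    """
    X = train.X.to_numpy(float)
    y = train.y.to_numpy(int)
    if len(np.unique(y)) < 2:
        raise StratificationError("both outcome classes are required")

    if len(alphas) == 1:
        best_alpha, best_f1 = alphas[0], float("nan")
    else:
        # Cross-validated F1 per grid value, then the one-standard-error
        # rule: among values within one SE of the best mean F1, take the
        # strongest penalty (smallest alpha).  The CV F1 curve is typically
        # flat across weak penalties, and argmax alone would pick among them
        # by noise, letting uninformative features through.
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        folds = list(splitter.split(X, y))
        means, ses = {}, {}
        for alpha in alphas:
            scores = []
            for tr, va in folds:
                model = _lasso(alpha, len(tr), seed).fit(X[tr], y[tr])
                scores.append(f1_score(y[va], model.predict(X[va]), pos_label=1, zero_division=0))
            means[alpha] = float(np.mean(scores))
            ses[alpha] = float(np.std(scores, ddof=1) / np.sqrt(len(scores)))
        top = max(alphas, key=lambda a: means[a])
        floor = means[top] - ses[top]
        best_alpha = min((a for a in alphas if means[a] >= floor), key=float)
        best_f1 = means[best_alpha]

    rng = np.random.default_rng(seed)
    n = len(y)
    m = max(2, int(round(subsample * n)))
    counts = np.zeros(X.shape[1], dtype=int)
    for _ in range(n_models):
        rows = rng.choice(n, size=m, replace=False)
        if len(np.unique(y[rows])) < 2:
            continue
        model = _lasso(best_alpha, m, seed).fit(X[rows], y[rows])
        counts += (np.abs(model.coef_[0]) > 1e-8).astype(int)

    selection_counts = dict(zip(train.X.columns, (int(c) for c in counts)))
    stable = [c for c, cnt in selection_counts.items() if cnt >= min_count]
    fallback = False
    if not stable:
        warnings.warn("stability selection kept no feature; falling back to all features")
        stable = list(train.X.columns)
        fallback = True
    return StabilityResult(
        alpha=float(best_alpha),
        f1_at_alpha=float(best_f1),
        selection_counts=selection_counts,
        stable_features=stable,
        n_models=n_models,
        fallback=fallback,
    )


def similarity_feature_set(stability: StabilityResult, matrix: FeatureMatrix) -> list[str]:
    """Stable features used by the similarity metric.

    One-hot new-treatment columns are excluded: the new treatment is the
    decision under evaluation and must not drive patient similarity.
    """
    return [c for c in stability.stable_features if matrix.provenance.get(c) != "new_onehot"]
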