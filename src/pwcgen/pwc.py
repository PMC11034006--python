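"""Parcelwise sex classifiers (pwC): nested CV, confound control, scoring.

One independent SVM classifier is trained per parcel on that parcel's
connectivity profile. Within-sample performance comes from a repeated,
stratified outer cross-validation with a hyperparameter grid search
nested inside each outer training fold; every accuracy reported anywhere
in the package is a *balanced* accuracy (mean of per-class recalls).

Age is removed from the features in a CV-consistent way: within each
outer training fold a per-feature linear age model is fitted on the
training subjects only and then applied to both the training and the
held-out subjects, so no information can leak from test to train.
Feature standardization follows the same rule. The same discipline
carries over to cross-sample application: the confound model and
standardization fitted on the full training sample are applied to the
test sample's features using the test subjects' ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, DegenerateDataError, LeakageError

__all__ = [
    "ClassifierConfig",
    "ConfoundModel",
    "AccuracyMap",
    "ParcelModel",
    "TrainedParcelModelSet",
    "fit_confound_model",
    "residualize",
    "balanced_accuracy",
    "cv_parcel_accuracy",
    "fit_final_models",
    "test_across_sample",
]

_VALID_KERNELS = ("linear", "rbf")


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameter search space and CV layout for the per-parcel SVMs.

    Defaults follow a standard log grid for C and gamma with a 10-fold
    outer CV repeated five times and a 5-fold inner grid search.
    """

    kernels: tuple[str, ...] = ("linear", "rbf")
    C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = ("scale", 0.001, 0.01, 0.1)
    outer_folds: int = 10
    repeats: int = 5
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.kernels or any(k not in _VALID_KERNELS for k in self.kernels):
            raise ConfigurationError(
                f"kernels must be a non-empty subset of {_VALID_KERNELS}"
            )
        if not self.C_grid or any(c <= 0 for c in self.C_grid):
            raise ConfigurationError("C_grid must be non-empty and positive")
        if not self.gamma_grid or any(
            (g != "scale") and (not float(g) > 0) for g in self.gamma_grid
        ):
            raise ConfigurationError(
                "gamma_grid entries must be positive or the 'scale' token"
            )
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ConfigurationError("fold counts must be >= 2")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")

    def param_grid(self) -> list[dict]:
        """Deterministically ordered (kernel, C, gamma) combinations.

        The linear kernel does not use gamma, so it contributes one entry
        per C value only.
        """
        grid: list[dict] = []
        for kernel in self.kernels:
            for c in self.C_grid:
                if kernel == "linear":
                    grid.append({"kernel": "linear", "C": float(c)})
                else:
                    for g in self.gamma_grid:
                        gamma = g if g == "scale" else float(g)
                        grid.append({"kernel": "rbf", "C": float(c), "gamma": gamma})
        return grid

    def restricted(self, kernels: tuple[str, ...] = ("rbf",)) -> "ClassifierConfig":
        """Copy of this config with the kernel choice restricted."""
        return replace(self, kernels=kernels)


@dataclass
class ConfoundModel:
    """Per-feature linear age model: feature ~ intercept + slope * age."""

    intercept: np.ndarray
    slope: np.ndarray

    def __post_init__(self) -> None:
        self.intercept = np.asarray(self.intercept, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)
        if self.intercept.shape != self.slope.shape:
            raise ConfigurationError("intercept/slope shape mismatch")
        if not (np.isfinite(self.intercept).all() and np.isfinite(self.slope).all()):
            raise ConfigurationError("confound coefficients must be finite")

    @property
    def n_features(self) -> int:
        return self.intercept.size


@dataclass
class AccuracyMap:
    """One balanced accuracy per parcel for a (train, eval) sample pair."""

    values: np.ndarray
    train_sample: str = ""
    eval_sample: str = ""
    mode: str = "within_cv"  # {"within_cv", "across_sample"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ConfigurationError("accuracy map must be one value per parcel")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ConfigurationError("balanced accuracies must lie in [0, 1]")
        if self.mode not in ("within_cv", "across_sample"):
            raise ConfigurationError(f"bad mode {self.mode!r}")

    @property
    def n_parcels(self) -> int:
        return self.values.size


@dataclass
class ParcelModel:
    """Everything needed to apply one parcel's classifier to new data."""

    confound: ConfoundModel
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    params: dict
    classifier: SVC


@dataclass
class TrainedParcelModelSet:
    """Fitted per-parcel models plus the training-sample bookkeeping."""

    models: list[ParcelModel]
    classes: tuple[str, ...]
    config: ClassifierConfig
    train_sample: str = ""
    subject_ids: tuple[str, ...] = ()

    @property
    def n_parcels(self) -> int:
        return len(self.models)


def fit_confound_model(x_train: np.ndarray, age_train: np.ndarray) -> ConfoundModel:
    """Per-feature OLS of feature on [1, age], fitted on training data only."""
    x = np.asarray(x_train, dtype=float)
    age = np.asarray(age_train, dtype=float)
    if x.ndim != 2:
        raise ConfigurationError("x_train must be 2-D (subjects x features)")
    if x.shape[0] != age.size:
        raise ConfigurationError("x_train rows and age_train length differ")
    if x.shape[0] < 3:
        raise DegenerateDataError("need >= 3 subjects to fit the confound model")
    if np.ptp(age) == 0:
        raise DegenerateDataError("constant age: slope unidentifiable")
    design = np.column_stack([np.ones(age.size), age])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return ConfoundModel(intercept=beta[0], slope=beta[1])


def residualize(
    x: np.ndarray, ages: np.ndarray, model: ConfoundModel
) -> np.ndarray:
    """Remove the modelled age effect: x - (intercept + slope * age)."""
    x = np.asarray(x, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.n_features:
        raise ConfigurationError(
            f"feature count {x.shape[-1]} does not match model ({model.n_features})"
        )
    if x.shape[0] != ages.size:
        raise ConfigurationError("x rows and ages length differ")
    return x - (model.intercept[None, :] + np.outer(ages, model.slope))


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recalls; for two classes, (TPR + TNR) / 2."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ConfigurationError("y_true and y_pred must have the same length")
    if np.unique(y_true).size < 2:
        raise DegenerateDataError(
            "balanced accuracy undefined: y_true contains a single class"
        )
    return float(balanced_accuracy_score(y_true, y_pred))


def _parcel_seed(seed: int, parcel: int) -> int:
    # stable, parallelism-independent per-parcel stream
    return (int(seed) * 1_000_003 + int(parcel) * 7_919 + 17) % (2**31 - 1)


def _encode_labels(labels) -> tuple[np.ndarray, tuple[str, ...]]:
    labels = np.asarray(labels)
    classes = tuple(sorted(np.unique(labels).tolist()))
    if len(classes) != 2:
        raise DegenerateDataError(
            f"need exactly two classes, got {classes}"
        )
    y = (labels == classes[1]).astype(int)
    return y, classes


def _fit_scaler(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scaler = StandardScaler().fit(x)
    return scaler.mean_, scaler.scale_


def _apply_scaler(x: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (x - mean[None, :]) / scale[None, :]


def _inner_select(
    x: np.ndarray, y: np.ndarray, config: ClassifierConfig, seed: int
) -> dict:
    """Inner stratified grid search; best combo by mean balanced accuracy.

    Ties keep the first combination in grid order, which makes selection
    deterministic.
    """
    skf = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=seed
    )
    splits = list(skf.split(x, y))
    best_params: dict | None = None
    best_score = -np.inf
    for params in config.param_grid():
        scores = []
        for tr, te in splits:
            clf = SVC(**params).fit(x[tr], y[tr])
            scores.append(balanced_accuracy_score(y[te], clf.predict(x[te])))
        score = float(np.mean(scores))
        if score > best_score:
            best_score = score
            best_params = params
    assert best_params is not None
    return best_params


def _fold_transform(
    x: np.ndarray, ages: np.ndarray, train_idx: np.ndarray
) -> tuple[ConfoundModel, np.ndarray, np.ndarray]:
    """Fit the fold's confound model and scaler on the training rows only.

    Exposed for the leakage audit: the returned fits depend solely on
    ``x[train_idx]`` and ``ages[train_idx]``.
    """
    confound = fit_confound_model(x[train_idx], ages[train_idx])
    x_tr = residualize(x[train_idx], ages[train_idx], confound)
    mean, scale = _fit_scaler(x_tr)
    return confound, mean, scale


def _cv_one_parcel(
    x: np.ndarray,
    y: np.ndarray,
    ages: np.ndarray,
    splits: list,
    config: ClassifierConfig,
    parcel: int,
) -> float:
    accs = []
    inner_seed = _parcel_seed(config.seed, parcel)
    for train_idx, test_idx in splits:
        if np.unique(y[train_idx]).size < 2 or np.unique(y[test_idx]).size < 2:
            raise DegenerateDataError(
                "a CV fold is missing a class; sample too small or imbalanced"
            )
        confound, mean, scale = _fold_transform(x, ages, train_idx)
        x_tr = _apply_scaler(
            residualize(x[train_idx], ages[train_idx], confound), mean, scale
        )
        x_te = _apply_scaler(
            residualize(x[test_idx], ages[test_idx], confound), mean, scale
        )
        params = _inner_select(x_tr, y[train_idx], config, inner_seed)
        clf = SVC(**params).fit(x_tr, y[train_idx])
        accs.append(balanced_accuracy_score(y[test_idx], clf.predict(x_te)))
    return float(np.mean(accs))


def cv_parcel_accuracy(
    profiles: np.ndarray,
    labels,
    ages,
    config: ClassifierConfig,
    n_jobs: int = 1,
    sample_name: str = "",
) -> AccuracyMap:
    """Within-sample accuracy map from repeated nested cross-validation.

    Parameters
    ----------
    profiles : array (n_subjects, P, P-1)
        Per-parcel feature blocks (see :func:`pwcgen.connectome.stack_profiles`).
    labels : sex labels, one per subject.
    ages : ages in years, one per subject.
    config : CV layout and hyperparameter grids.
    n_jobs : per-parcel parallelism; results are independent of it.

    Each parcel's value is the mean balanced accuracy over
    ``outer_folds * repeats`` held-out folds; within every outer training
    fold the confound model, the standardization and the selected
    hyperparameters are fitted without the held-out subjects.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 3:
        raise ConfigurationError("profiles must be (n_subjects, P, features)")
    y, _ = _encode_labels(labels)
    ages = np.asarray(ages, dtype=float)
    n, n_parcels, _ = profiles.shape
    if y.size != n or ages.size != n:
        raise ConfigurationError("labels/ages length does not match profiles")
    if min(np.bincount(y)) < config.outer_folds:
        raise DegenerateDataError(
            "minority class smaller than outer fold count; folds would miss a class"
        )
    outer = RepeatedStratifiedKFold(
        n_splits=config.outer_folds,
        n_repeats=config.repeats,
        random_state=config.seed,
    )
    splits = list(outer.split(np.zeros(n), y))
    tasks = (
        delayed(_cv_one_parcel)(profiles[:, p, :], y, ages, splits, config, p)
        for p in range(n_parcels)
    )
    values = Parallel(n_jobs=n_jobs)(tasks)
    return AccuracyMap(
        np.asarray(values),
        train_sample=sample_name,
        eval_sample=sample_name,
        mode="within_cv",
    )


def _fit_one_parcel(
    x: np.ndarray,
    y: np.ndarray,
    ages: np.ndarray,
    config: ClassifierConfig,
    parcel: int,
) -> ParcelModel:
    confound = fit_confound_model(x, ages)
    x_r = residualize(x, ages, confound)
    mean, scale = _fit_scaler(x_r)
    x_s = _apply_scaler(x_r, mean, scale)
    params = _inner_select(x_s, y, config, _parcel_seed(config.seed, parcel))
    clf = SVC(**params).fit(x_s, y)
    return ParcelModel(confound, mean, scale, params, clf)


def fit_final_models(
    profiles: np.ndarray,
    labels,
    ages,
    config: ClassifierConfig,
    restrict_rbf: bool = True,
    subject_ids=(),
    sample_name: str = "",
    n_jobs: int = 1,
) -> TrainedParcelModelSet:
    """Refit one final classifier per parcel on the full training sample.

    Hyperparameters are selected by the inner grid search on the whole
    sample; the confound model and standardization are fitted on the
    whole sample. For cross-sample application the kernel choice is
    restricted to rbf (``restrict_rbf=True``).
    """
    profiles = np.asarray(profiles, dtype=float)
    y, classes = _encode_labels(labels)
    ages = np.asarray(ages, dtype=float)
    cfg = config.restricted(("rbf",)) if restrict_rbf else config
    n_parcels = profiles.shape[1]
    tasks = (
        delayed(_fit_one_parcel)(profiles[:, p, :], y, ages, cfg, p)
        for p in range(n_parcels)
    )
    models = Parallel(n_jobs=n_jobs)(tasks)
    return TrainedParcelModelSet(
        models=list(models),
        classes=classes,
        config=cfg,
        train_sample=sample_name,
        subject_ids=tuple(subject_ids),
    )


def test_across_sample(
    models: TrainedParcelModelSet,
    test_profiles: np.ndarray,
    test_labels,
    test_ages,
    test_subject_ids=(),
    eval_sample: str = "",
    allow_overlap: bool = False,
) -> AccuracyMap:
    """Apply trained parcel models to a disjoint test sample.

    Test features are residualized with the training-fitted confound
    model (using the test subjects' ages) and standardized with the
    training-fitted parameters; each parcel is scored with balanced
    accuracy.
    """
    test_profiles = np.asarray(test_profiles, dtype=float)
    y_test, classes = _encode_labels(test_labels)
    if classes != models.classes:
        raise ConfigurationError(
            f"test classes {classes} differ from training classes {models.classes}"
        )
    test_ages = np.asarray(test_ages, dtype=float)
    if not allow_overlap and models.subject_ids and len(tuple(test_subject_ids)):
        overlap = set(models.subject_ids) & set(test_subject_ids)
        if overlap:
            raise LeakageError(
                f"train and test samples share {len(overlap)} subject(s), "
                f"e.g. {sorted(overlap)[:3]}"
            )
    if test_profiles.shape[1] != models.n_parcels:
        raise ConfigurationError("parcel count mismatch between models and data")
    values = np.empty(models.n_parcels)
    for p, model in enumerate(models.models):
        x = residualize(test_profiles[:, p, :], test_ages, model.confound)
        x = _apply_scaler(x, model.scaler_mean, model.scaler_scale)
        values[p] = balanced_accuracy_score(y_test, model.classifier.predict(x))
    return AccuracyMap(
        values,
        train_sample=models.train_sample,
        eval_sample=eval_sample,
        mode="across_sample",
    )
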