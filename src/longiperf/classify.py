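"""LASSO feature selection and stepwise one-vs-rest RBF-SVM classification.

The 3-class surveillance decision (progressive disease vs pseudoprogression
vs stable disease) is made in two binary stages, each an independent
pipeline of

    standardise -> L1-penalised logistic selection -> RBF-SVM,

one trained for "SD vs rest" and one for "PD vs rest", combined by a fixed
precedence rule (PD wins conflicts: a missed progression is the costlier
clinical error).  Estimators follow the scikit-learn protocol (``fit`` /
``predict`` / ``get_params``; fitted attributes carry trailing
underscores) and compose with sklearn model selection.

All data-dependent choices — the LASSO penalty (inner stratified CV,
deviance criterion, one-standard-error rule) and the SVM grid (C and a
gamma scale around 1/n_features) — are functions of the training data only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .io_core import CLASS_LABELS, logger


def _as_array(X):
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    return np.asarray(X, dtype=np.float64), names


def _effective_folds(y: np.ndarray, requested: int) -> int:
    _, counts = np.unique(y, return_counts=True)
    return int(max(2, min(requested, counts.min())))


class L1LogisticSelector(SelectorMixin, BaseEstimator):
    """Feature selection by an L1-penalised logistic regression path.

    The penalty grid runs from the smallest lambda that zeroes every
    coefficient down to ``lambda_min_ratio`` of it.  Lambda is chosen by
    stratified inner cross-validation on the binomial deviance with the
    one-standard-error rule (the sparsest model within one SE of the
    minimum).  If the chosen lambda selects nothing, the largest lambda on
    the path with at least one surviving coefficient is used; if the whole
    path is empty the single feature with the largest absolute point-biserial
    correlation is returned, so selection never comes back empty.

    Parameters
    ----------
    n_lambdas : int
        Path resolution.
    lambda_min_ratio : float
        Ratio of smallest to largest penalty on the path.
    inner_folds : int
        Stratified CV folds for the deviance criterion (reduced
        automatically if a class is too small).
    one_se : bool
        Apply the 1-SE rule; otherwise take the deviance minimiser.
    lambda_grid : sequence of float, optional
        Explicit penalty grid overriding the automatic one.
    """

    def __init__(
        self,
        n_lambdas: int = 12,
        lambda_min_ratio: float = 1e-3,
        inner_folds: int = 3,
        one_se: bool = True,
        lambda_grid=None,
        random_state=None,
    ):
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.inner_folds = inner_folds
        self.one_se = one_se
        self.lambda_grid = lambda_grid
        self.random_state = random_state

    def _fit_at(self, X, y, lam: float) -> LogisticRegression:
        C = 1.0 / (len(y) * lam)
        return LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000
        ).fit(X, y)

    def fit(self, X, y):
        X, names = _as_array(X)
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"selector requires binary labels, got {classes}")
        y01 = (y == classes[1]).astype(int)
        if min(np.bincount(y01)) < 2:
            raise ValueError("selection requires >= 2 samples per class")
        n, d = X.shape
        self.n_features_in_ = d
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)

        if self.lambda_grid is not None:
            grid = np.sort(np.asarray(self.lambda_grid, dtype=float))[::-1]
        else:
            resid = y01 - y01.mean()
            lam_max = np.abs(X.T @ resid).max() / n
            lam_max = max(lam_max, 1e-12)
            grid = np.logspace(
                np.log10(lam_max), np.log10(lam_max * self.lambda_min_ratio),
                self.n_lambdas,
            )

        k = _effective_folds(y01, self.inner_folds)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=self.random_state)
        dev = np.zeros((len(grid), k))
        for f, (tr, va) in enumerate(skf.split(X, y01)):
            for g, lam in enumerate(grid):
                model = self._fit_at(X[tr], y01[tr], lam)
                p = model.predict_proba(X[va])
                dev[g, f] = 2 * log_loss(
                    y01[va], p, labels=[0, 1], normalize=True
                )
        mean_dev = dev.mean(axis=1)
        se_dev = dev.std(axis=1, ddof=1) / np.sqrt(k)
        best = int(np.argmin(mean_dev))
        if self.one_se:
            thresh = mean_dev[best] + se_dev[best]
            chosen = int(np.nonzero(mean_dev <= thresh)[0][0])  # largest lambda
        else:
            chosen = best
        self.lambda_ = float(grid[chosen])
        self.cv_deviance_ = pd.DataFrame(
            {"lambda": grid, "mean_deviance": mean_dev, "se_deviance": se_dev}
        )

        model = self._fit_at(X, y01, self.lambda_)
        support = model.coef_.ravel() != 0
        if not support.any():
            for lam in grid[grid < self.lambda_]:
                model = self._fit_at(X, y01, lam)
                support = model.coef_.ravel() != 0
                if support.any():
                    self.lambda_ = float(lam)
                    break
        if not support.any():
            # degenerate path: keep the strongest univariate feature
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            corr = np.abs((X - X.mean(axis=0)).T @ (y01 - y01.mean())) / sd
            support = np.zeros(d, dtype=bool)
            support[int(np.argmax(corr))] = True
        self.support_ = support
        self.coef_ = model.coef_.ravel()
        if names is not None:
            self.selected_features_ = [names[i] for i in np.nonzero(support)[0]]
        else:
            self.selected_features_ = list(np.nonzero(support)[0])
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class BinaryStageClassifier(ClassifierMixin, BaseEstimator):
    """One binary stage: standardise -> LASSO selection -> RBF-SVM.

    Standardisation statistics, the selected feature set and the SVM
    hyperparameters (C over ``C_grid``; gamma = factor / n_selected over
    ``gamma_factors``, chosen by inner stratified CV accuracy) all come
    from the training data alone.  Classes are weighted inversely to their
    frequency (``class_weight="balanced"``), since surveillance cohorts are
    imbalanced towards progression.
    """

    def __init__(
        self,
        C_grid=(0.1, 1.0, 10.0, 100.0),
        gamma_factors=(0.1, 1.0, 10.0),
        inner_folds: int = 3,
        n_lambdas: int = 12,
        lambda_min_ratio: float = 1e-3,
        one_se: bool = True,
        random_state=None,
    ):
        self.C_grid = C_grid
        self.gamma_factors = gamma_factors
        self.inner_folds = inner_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.one_se = one_se
        self.random_state = random_state

    def fit(self, X, y):
        Xa, names = _as_array(X)
        Xa, y = check_X_y(Xa, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"binary stage requires 2 classes, got {self.classes_}")
        self.n_features_in_ = Xa.shape[1]
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)

        self.scaler_ = StandardScaler().fit(Xa)
        Xs = self.scaler_.transform(Xa)
        self.selector_ = L1LogisticSelector(
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            inner_folds=self.inner_folds,
            one_se=self.one_se,
            random_state=self.random_state,
        )
        if names is not None:
            self.selector_.fit(pd.DataFrame(Xs, columns=names), y)
        else:
            self.selector_.fit(Xs, y)
        Xsel = Xs[:, self.selector_.support_]
        self.selected_features_ = self.selector_.selected_features_

        d = Xsel.shape[1]
        k = _effective_folds(y, self.inner_folds)
        grid = {
            "C": list(self.C_grid),
            "gamma": [f / d for f in self.gamma_factors],
        }
        search = GridSearchCV(
            SVC(kernel="rbf", class_weight="balanced"),
            grid,
            cv=StratifiedKFold(n_splits=k, shuffle=True, random_state=self.random_state),
            scoring="accuracy",
            n_jobs=None,
        ).fit(Xsel, y)
        self.svm_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.inner_cv_accuracy_ = float(search.best_score_)
        logger.debug(
            "stage fit: %d/%d features, lambda=%.4g, C=%g, gamma=%.4g, "
            "inner-CV acc=%.3f",
            d,
            Xa.shape[1],
            self.selector_.lambda_,
            self.best_params_["C"],
            self.best_params_["gamma"],
            self.inner_cv_accuracy_,
        )
        return self

    def _transform(self, X):
        check_is_fitted(self, "svm_")
        Xa, _ = _as_array(X)
        Xa = check_array(Xa)
        return self.scaler_.transform(Xa)[:, self.selector_.support_]

    def decision_function(self, X):
        return self.svm_.decision_function(self._transform(X))

    def predict(self, X):
        return self.svm_.predict(self._transform(X))


class StepwiseGliomaClassifier(ClassifierMixin, BaseEstimator):
    """Two one-vs-rest stages combined into a 3-class prediction.

    Stage "PD vs rest" and stage "SD vs rest" are fit independently; the
    combination rule is: PD if the PD stage fires, else SD if the SD stage
    fires, else PsP.  A conflict (both fire) resolves to PD.
    """

    REST = "rest"

    def __init__(
        self,
        C_grid=(0.1, 1.0, 10.0, 100.0),
        gamma_factors=(0.1, 1.0, 10.0),
        inner_folds: int = 3,
        n_lambdas: int = 12,
        lambda_min_ratio: float = 1e-3,
        one_se: bool = True,
        random_state=None,
    ):
        self.C_grid = C_grid
        self.gamma_factors = gamma_factors
        self.inner_folds = inner_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.one_se = one_se
        self.random_state = random_state

    def _stage_params(self, seed_offset: int) -> dict:
        rs = self.random_state
        if rs is not None:
            rs = (int(rs) + seed_offset) % (2**31)
        return dict(
            C_grid=self.C_grid,
            gamma_factors=self.gamma_factors,
            inner_folds=self.inner_folds,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            one_se=self.one_se,
            random_state=rs,
        )

    def fit(self, X, y):
        y = np.asarray(y, dtype=object)
        unknown = set(y) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)}")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.classes_ = np.asarray(CLASS_LABELS, dtype=object)
        y_sd = np.where(y == "SD", "SD", self.REST)
        y_pd = np.where(y == "PD", "PD", self.REST)
        self.stage_sd_ = BinaryStageClassifier(**self._stage_params(1)).fit(X, y_sd)
        self.stage_pd_ = BinaryStageClassifier(**self._stage_params(2)).fit(X, y_pd)
        return self

    def predict(self, X):
        check_is_fitted(self, "stage_pd_")
        is_pd = self.stage_pd_.predict(X) == "PD"
        is_sd = self.stage_sd_.predict(X) == "SD"
        out = np.where(is_pd, "PD", np.where(is_sd, "SD", "PsP"))
        return out.astype(object)

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "stage_pd_")
        return {
            "classes": list(self.classes_),
            "feature_names": [str(n) for n in getattr(self, "feature_names_in_", [])],
            "stages": {
                "SD": _stage_to_dict(self.stage_sd_),
                "PD": _stage_to_dict(self.stage_pd_),
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @staticmethod
    def load(path: str | Path) -> "FrozenStepwiseClassifier":
        return FrozenStepwiseClassifier(json.loads(Path(path).read_text()))


def _stage_to_dict(stage: BinaryStageClassifier) -> dict:
    svm = stage.svm_
    return {
        "target": str(stage.classes_[stage.classes_ != StepwiseGliomaClassifier.REST][0]),
        "scaler_mean": stage.scaler_.mean_.tolist(),
        "scaler_scale": stage.scaler_.scale_.tolist(),
        "support": np.nonzero(stage.selector_.support_)[0].tolist(),
        "selected_features": [str(f) for f in stage.selected_features_],
        "lasso_lambda": stage.selector_.lambda_,
        "svm_classes": [str(c) for c in svm.classes_],
        "support_vectors": svm.support_vectors_.tolist(),
        "dual_coef": svm.dual_coef_.tolist(),
        "intercept": svm.intercept_.tolist(),
        "gamma": float(svm._gamma),
        "C": float(svm.C),
    }


class _FrozenStage:
    """Prediction-only reconstruction of a persisted binary stage."""

    def __init__(self, d: dict):
        self.mean = np.asarray(d["scaler_mean"])
        self.scale = np.asarray(d["scaler_scale"])
        self.support = np.asarray(d["support"], dtype=int)
        self.sv = np.asarray(d["support_vectors"])
        self.dual = np.asarray(d["dual_coef"]).ravel()
        self.b = float(np.asarray(d["intercept"]).ravel()[0])
        self.gamma = float(d["gamma"])
        self.classes = d["svm_classes"]
        self.target = d["target"]

    def decision_function(self, X) -> np.ndarray:
        Xa, _ = _as_array(X)
        Xs = ((Xa - self.mean) / self.scale)[:, self.support]
        d2 = ((Xs[:, None, :] - self.sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual + self.b

    def predict(self, X) -> np.ndarray:
        dec = self.decision_function(X)
        return np.where(dec > 0, self.classes[1], self.classes[0]).astype(object)


class FrozenStepwiseClassifier:
    """Prediction-only stepwise classifier rebuilt from JSON."""

    def __init__(self, d: dict):
        self.classes_ = np.asarray(d["classes"], dtype=object)
        self.feature_names_ = d.get("feature_names", [])
        self.stage_sd = _FrozenStage(d["stages"]["SD"])
        self.stage_pd = _FrozenStage(d["stages"]["PD"])

    def predict(self, X):
        if self.feature_names_ and isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names_ if f not in X.columns]
            if missing:
                raise ValueError(f"missing features {missing[:5]}")
            X = X[self.feature_names_]
        is_pd = self.stage_pd.predict(X) == "PD"
        is_sd = self.stage_sd.predict(X) == "SD"
        return np.where(is_pd, "PD", np.where(is_sd, "SD", "PsP")).astype(object)


# -- thin functional wrappers over the estimators --------------------------


def lasso_select(X, y, inner_folds: int = 3, seed=None, **kwargs):
    """Select features for a binary problem; returns (names_or_indices, lambda)."""
    sel = L1LogisticSelector(
        inner_folds=inner_folds, random_state=seed, **kwargs
    ).fit(X, y)
    return sel.selected_features_, sel.lambda_


def fit_stage(X, y_binary, seed=None, **kwargs) -> BinaryStageClassifier:
    return BinaryStageClassifier(random_state=seed, **kwargs).fit(X, y_binary)


def stepwise_predict(model, X):
    """3-class prediction through the precedence rule (PD > SD > PsP)."""
    return model.predict(X)
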