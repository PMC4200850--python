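"""Linear discriminant link-prediction model on moving-average features.

The activity score of drug d_i under assay conditions c_q is an affine
function of the five MA features:

    S_ij(c_q) = a_0 + a' * p(c_l) theta_5
              + a''_sx Δθ(s_x) + a''_au Δθ(a_u)
              + a''_ot Δθ(o_t) + a''_te Δθ(t_j)

A monotone link maps the score to a probability; the link is predicted as
a positive outcome (L = 1) when p exceeds the cutoff, strictly. Models are
either refit by linear discriminant analysis on labeled feature vectors or
loaded from a coefficient file; the package ships the published reference
coefficients in ``data/reference_model.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from .errors import DataError, NumericalError
from .features import FEATURE_NAMES, AlmaFeaturizer

__all__ = [
    "AlmaModel",
    "AlmaClassifier",
    "reference_model",
    "load_model",
    "save_model",
    "score",
    "probability",
    "fit_lda",
    "predict_table",
]

#: JSON coefficient keys, aligned with the feature-vector columns.
COEF_KEYS: tuple[str, ...] = ("quality", "sx", "au", "ot", "te")


@dataclass
class AlmaModel:
    """Affine score model: intercept plus five feature coefficients.

    ``coef`` is ordered as the feature vector: quality term, then the
    measure / assay / organism / target deviations.
    """

    intercept: float
    coef: np.ndarray
    cutoff: float = 0.5
    link: str = "logistic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=float)
        if coef.shape != (5,):
            raise DataError("AlmaModel requires exactly five coefficients")
        if not (np.isfinite(coef).all() and np.isfinite(self.intercept)):
            raise DataError("model coefficients must be finite")
        self.coef = coef

    def score(self, features: np.ndarray) -> np.ndarray:
        """Affine score S = a_0 + a . f for one vector or a matrix of rows."""
        f = np.asarray(features, dtype=float)
        return self.intercept + f @ self.coef

    def probability(self, scores) -> np.ndarray:
        """Monotone score-to-probability link.

        The logistic link sigma(S) is exact for a two-class discriminant
        whose intercept encodes the boundary at posterior 0.5; for the
        fixed reference coefficients it is a documented approximation.
        """
        s = np.asarray(scores, dtype=float)
        if self.link != "logistic":
            raise DataError(f"unknown link {self.link!r}")
        return expit(s)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predicted labels: 1 where probability strictly exceeds cutoff."""
        p = self.probability(self.score(features))
        return (p > self.cutoff).astype(int)

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "coef": {k: float(v) for k, v in zip(COEF_KEYS, self.coef)},
            "cutoff": float(self.cutoff),
            "link": self.link,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AlmaModel":
        try:
            coef = np.array([payload["coef"][k] for k in COEF_KEYS], dtype=float)
            return cls(
                intercept=float(payload["intercept"]),
                coef=coef,
                cutoff=float(payload.get("cutoff", 0.5)),
                link=str(payload.get("link", "logistic")),
                meta=dict(payload.get("meta", {})),
            )
        except KeyError as exc:
            raise DataError(f"model JSON lacks required key: {exc}") from None


def reference_model() -> AlmaModel:
    """The shipped reference model with the published coefficients."""
    text = (
        resources.files("almaentropy") / "data" / "reference_model.json"
    ).read_text()
    return AlmaModel.from_dict(json.loads(text))


def load_model(path: str | Path) -> AlmaModel:
    """Read a model from a coefficient JSON file."""
    return AlmaModel.from_dict(json.loads(Path(path).read_text()))


def save_model(model: AlmaModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1) + "\n")


def score(model: AlmaModel, features: np.ndarray) -> np.ndarray:
    """Thin functional wrapper over :meth:`AlmaModel.score`."""
    return model.score(features)


def probability(model: AlmaModel, scores) -> np.ndarray:
    """Thin functional wrapper over :meth:`AlmaModel.probability`."""
    return model.probability(scores)


class AlmaClassifier(ClassifierMixin, BaseEstimator):
    """Two-class linear discriminant on the five MA features.

    A thin estimator over scikit-learn's pooled-covariance LDA that
    additionally exposes the fitted coefficients as an :class:`AlmaModel`
    and the canonical correlation of the discriminant as a diagnostic.

    Parameters
    ----------
    cutoff : float, default 0.5
        Probability cutoff; predictions are 1 strictly above it.
    shrinkage : float or None, default None
        Ledoit-Wolf style covariance shrinkage in [0, 1]; required when the
        pooled within-class covariance is singular.
    priors : array-like or None
        Class priors; empirical by default.

    Attributes
    ----------
    coef_ : ndarray of shape (5,)
        Discriminant coefficients on the feature columns.
    intercept_ : float
        Intercept placing the decision boundary at posterior 0.5.
    model_ : AlmaModel
        The fitted coefficients as a portable model object.
    canonical_correlation_ : float
        Pearson correlation between the discriminant score and the labels.
    chi2_ : float
        Bartlett's chi-square of the discriminant, from Wilks' lambda.
    """

    def __init__(
        self,
        *,
        cutoff: float = 0.5,
        shrinkage: Optional[float] = None,
        priors: Optional[Sequence[float]] = None,
    ) -> None:
        self.cutoff = cutoff
        self.shrinkage = shrinkage
        self.priors = priors

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AlmaClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise DataError("feature matrix must be two-dimensional")
        if len(X) != len(y):
            raise DataError("features and labels differ in length")
        if len(X) < 6:
            raise DataError("fitting requires at least 6 records")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise DataError(
                "fitting requires both classes 0 and 1 to be present"
            )
        self._check_pooled_covariance(X, y)
        if self.shrinkage is None:
            lda = LinearDiscriminantAnalysis(solver="svd", priors=self.priors)
        else:
            lda = LinearDiscriminantAnalysis(
                solver="eigen", shrinkage=self.shrinkage, priors=self.priors
            )
        lda.fit(X, y)
        self.lda_ = lda
        self.classes_ = lda.classes_
        self.coef_ = lda.coef_.ravel().copy()
        self.intercept_ = float(lda.intercept_[0])
        self.n_features_in_ = X.shape[1]

        scores = lda.decision_function(X)
        rc = float(np.corrcoef(scores, y.astype(float))[0, 1])
        self.canonical_correlation_ = rc
        n, p = X.shape
        wilks = max(1.0 - rc**2, np.finfo(float).tiny)
        self.chi2_ = float(-(n - 1 - (p + 2) / 2.0) * np.log(wilks))
        self.model_ = AlmaModel(
            intercept=self.intercept_,
            coef=self.coef_,
            cutoff=self.cutoff,
            link="logistic",
            meta={
                "N": int(n),
                "Rc": rc,
                "chi2": self.chi2_,
                "source": "refit linear discriminant",
                "features": list(FEATURE_NAMES)[:p],
            },
        )
        return self

    def _check_pooled_covariance(self, X: np.ndarray, y: np.ndarray) -> None:
        pooled = np.zeros((X.shape[1], X.shape[1]))
        for c in (0, 1):
            xc = X[y == c]
            if len(xc) > 1:
                pooled += (len(xc) - 1) * np.cov(xc, rowvar=False)
        pooled /= max(len(X) - 2, 1)
        rank = np.linalg.matrix_rank(pooled, tol=1e-10 * np.trace(pooled) / len(pooled))
        if rank < X.shape[1] and self.shrinkage is None:
            raise NumericalError(
                "pooled within-class covariance is singular; refit with the "
                "shrinkage parameter set (e.g. shrinkage=1e-4)"
            )

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "lda_")
        return self.lda_.decision_function(np.asarray(X, dtype=float))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "lda_")
        return self.lda_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels via the strict probability cutoff (ties go to 0)."""
        p1 = self.predict_proba(X)[:, 1]
        return (p1 > self.cutoff).astype(int)


def fit_lda(
    features: np.ndarray,
    labels: Sequence[int],
    *,
    cutoff: float = 0.5,
    shrinkage: Optional[float] = None,
) -> AlmaModel:
    """Fit the linear discriminant and return the portable coefficient model."""
    clf = AlmaClassifier(cutoff=cutoff, shrinkage=shrinkage)
    clf.fit(np.asarray(features, dtype=float), np.asarray(labels))
    return clf.model_


def predict_table(
    model: AlmaModel,
    endpoints: pd.DataFrame,
    featurizer: AlmaFeaturizer,
) -> pd.DataFrame:
    """Score endpoint rows: one prediction per record.

    Returns the endpoint frame with ``score``, ``proba`` and ``label_pred``
    columns appended. The same compound under different condition tuples
    receives different scores whenever the conditions' moving averages
    differ.
    """
    out = endpoints.reset_index(drop=True).copy()
    if len(out) == 0:
        for col in ("score", "proba", "label_pred"):
            out[col] = pd.Series(dtype=float)
        out["label_pred"] = out["label_pred"].astype("Int64")
        return out
    feats = featurizer.transform(out)
    s = model.score(feats)
    p = model.probability(s)
    out["score"] = s
    out["proba"] = p
    out["label_pred"] = (p > model.cutoff).astype(int)
    return out
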