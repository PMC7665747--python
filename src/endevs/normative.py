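"""Normative-model stage: pluggable per-feature regression with predictive
uncertainty, cross-validated model criticism, and the explained-variance
feature filter.

A normative model maps covariates X (age, sex, site, ...) to a predictive
distribution over each biological feature, learned on a reference cohort.
The contract required downstream is minimal: per subject and feature a
predictive mean ``mu``, predictive variance ``sigma2``, and a learned
per-feature noise variance ``eta2`` — exactly the quantities entering the
standardized deviance.

Two backends satisfy the contract:

* ``"gp"`` (reference): one independent Gaussian-process regressor per
  feature — constant mean, ARD radial-basis kernel over the standardized
  design matrix plus a fitted white-noise term, hyperparameters optimized on
  the marginal likelihood.  Predictive variance grows away from the training
  hull, which is what makes out-of-distribution covariates produce large
  standardized deviances.
* ``"linear"``: Bayesian ridge regression per feature; much cheaper, useful
  when the covariate-feature map is near-linear or for quick checks.

Continuous covariates are z-scored with training-split statistics only;
categorical covariates are one-hot encoded against the training categories.

Model criticism runs seeded, shuffled k-fold cross-validation, computing
per-feature held-out r^2 = 1 - SSE/SST (which may be negative) and the
out-of-fold standardized deviance matrix, assembled in original subject
order.  Features whose mean r^2 over folds does not exceed a threshold
(0.2 by default) are flagged for exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import BayesianRidge
from sklearn.model_selection import KFold

from .deviance import NormativePrediction, standardized_deviance
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["CohortData", "ModelCriticism", "NormativeModel", "criticize"]


@dataclass
class CohortData:
    """Covariates and responses for one cohort.

    ``schema`` maps covariate column names to ``"continuous"`` or
    ``"categorical"``; columns absent from the schema are treated as
    continuous if numeric and categorical otherwise.
    """

    X: pd.DataFrame
    Y: pd.DataFrame
    schema: dict | None = None

    def __post_init__(self):
        self.X = pd.DataFrame(self.X)
        self.Y = pd.DataFrame(self.Y)
        if len(self.X) != len(self.Y):
            raise ValidationError("X and Y must have the same number of subjects")
        if len(self.X) < 2:
            raise ValidationError("a cohort needs at least 2 subjects")
        if self.X.isna().any().any() or self.Y.isna().any().any():
            raise ValidationError("missing values must be handled before modeling")

    @property
    def subject_ids(self):
        return list(self.Y.index)

    @property
    def feature_names(self):
        return list(self.Y.columns)


@dataclass(frozen=True)
class ModelCriticism:
    """Cross-validated explained variance and the resulting feature filter."""

    r2: np.ndarray
    folds: int
    threshold: float
    kept: np.ndarray
    feature_names: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or list(range(len(self.r2)))
        return pd.DataFrame({"feature": names, "r2": self.r2, "kept": self.kept})


class _Design:
    """Training-statistics-only covariate encoding (no leakage)."""

    def __init__(self, schema: dict | None):
        self.schema = schema or {}

    def fit(self, X: pd.DataFrame) -> "_Design":
        self.columns_ = list(X.columns)
        self.kinds_ = {}
        self.stats_ = {}
        self.categories_ = {}
        for col in self.columns_:
            kind = self.schema.get(
                col, "continuous" if pd.api.types.is_numeric_dtype(X[col]) else "categorical"
            )
            self.kinds_[col] = kind
            if kind == "continuous":
                mu = float(X[col].mean())
                sd = float(X[col].std(ddof=0))
                if sd == 0:
                    logger.warning("constant covariate %r; leaving unscaled", col)
                    sd = 1.0
                self.stats_[col] = (mu, sd)
            elif kind == "categorical":
                self.categories_[col] = sorted(pd.unique(X[col]).tolist())
            else:
                raise ValidationError(f"unknown covariate kind {kind!r} for {col!r}")
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.columns_:
            raise ValidationError(
                f"covariate columns {list(X.columns)} do not match training {self.columns_}"
            )
        blocks = []
        for col in self.columns_:
            if self.kinds_[col] == "continuous":
                mu, sd = self.stats_[col]
                blocks.append(((X[col].to_numpy(float) - mu) / sd)[:, None])
            else:
                cats = self.categories_[col]
                vals = X[col].to_numpy()
                blocks.append(np.column_stack([(vals == c).astype(float) for c in cats]))
        return np.hstack(blocks)


def _make_gp(n_dims: int, random_state: int) -> GaussianProcessRegressor:
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
        np.ones(n_dims), (1e-2, 1e3)
    ) + WhiteKernel(1e-1, (1e-10, 1e1))
    return GaussianProcessRegressor(
        kernel=kernel, n_restarts_optimizer=0, random_state=random_state
    )


class NormativeModel:
    """Independent per-feature regressors with predictive uncertainty.

    Parameters
    ----------
    backend : {"gp", "linear"}
        Reference Gaussian-process backend or a Bayesian-ridge fallback.
    schema : dict, optional
        Covariate name -> "continuous" | "categorical".
    random_state : int
        Seed for backend stochasticity (GP optimizer restarts).
    """

    def __init__(self, backend: str = "gp", schema: dict | None = None, random_state: int = 0):
        if backend not in ("gp", "linear"):
            raise ValidationError(f"unknown backend {backend!r}")
        self.backend = backend
        self.schema = schema
        self.random_state = random_state

    def fit(self, X, Y) -> "NormativeModel":
        X = pd.DataFrame(X)
        Y = pd.DataFrame(Y)
        data = CohortData(X, Y, self.schema)
        self.design_ = _Design(self.schema).fit(data.X)
        D = self.design_.transform(data.X)
        self.feature_names_ = data.feature_names
        self.y_mean_ = Y.to_numpy(float).mean(axis=0)
        sd = Y.to_numpy(float).std(axis=0, ddof=0)
        constant = sd == 0
        if constant.any():
            logger.warning("constant response feature(s): %s",
                           [n for n, c in zip(self.feature_names_, constant) if c])
        self.y_sd_ = np.where(constant, 1.0, sd)
        self.estimators_ = []
        ys = (Y.to_numpy(float) - self.y_mean_) / self.y_sd_
        for j in range(ys.shape[1]):
            if self.backend == "gp":
                est = _make_gp(D.shape[1], self.random_state)
            else:
                est = BayesianRidge()
            est.fit(D, ys[:, j])
            self.estimators_.append(est)
        return self

    def _noise_level(self, est) -> float:
        if self.backend == "gp":
            return float(est.kernel_.k2.noise_level)
        return float(1.0 / est.alpha_)

    def predict(self, X) -> NormativePrediction:
        """Predictive means, variances, and noise variances for new covariates."""
        if not hasattr(self, "estimators_"):
            raise ValidationError("model is not fitted")
        D = self.design_.transform(pd.DataFrame(X))
        n, m = D.shape[0], len(self.estimators_)
        mu = np.empty((n, m))
        sigma2 = np.empty((n, m))
        eta2 = np.empty(m)
        for j, est in enumerate(self.estimators_):
            mean_s, std_s = est.predict(D, return_std=True)
            noise = self._noise_level(est)
            scale2 = self.y_sd_[j] ** 2
            # predictive std from both backends includes the noise term;
            # split it out so sigma2 is the epistemic part only
            total_var = std_s**2 * scale2
            eta2[j] = noise * scale2
            sigma2[:, j] = np.maximum(total_var - eta2[j], 0.0)
            mu[:, j] = self.y_mean_[j] + self.y_sd_[j] * mean_s
        return NormativePrediction(mu=mu, sigma2=sigma2, eta2=eta2)


def criticize(
    X,
    Y,
    schema: dict | None = None,
    folds: int = 10,
    threshold: float = 0.2,
    backend: str = "gp",
    seed: int = 0,
):
    """Cross-validated model criticism plus the out-of-fold deviance matrix.

    Per fold: fit on the training split, compute per-feature held-out
    ``r2 = 1 - SSE/SST`` and the standardized deviance of held-out subjects.
    Folds where a feature is constant in the held-out split contribute no r2
    for that feature (logged).  Rows of the returned deviance matrix are in
    the original subject order.

    Returns
    -------
    criticism : ModelCriticism
    Z : pandas.DataFrame
        Out-of-fold signed standardized deviances, one row per subject.
    """
    if folds < 2:
        raise ValidationError(f"folds must be >= 2, got {folds}")
    if not (0.0 <= threshold < 1.0):
        raise ValidationError(f"threshold must be in [0, 1), got {threshold}")
    X = pd.DataFrame(X)
    Y = pd.DataFrame(Y)
    data = CohortData(X, Y, schema)
    yv = Y.to_numpy(float)
    n, m = yv.shape
    Z = np.full((n, m), np.nan)
    r2_folds = np.full((folds, m), np.nan)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for k, (train, test) in enumerate(kf.split(yv)):
        model = NormativeModel(backend=backend, schema=schema, random_state=seed).fit(
            X.iloc[train], Y.iloc[train]
        )
        pred = model.predict(X.iloc[test])
        Z[test] = standardized_deviance(yv[test], pred)
        sse = ((yv[test] - pred.mu) ** 2).sum(axis=0)
        sst = ((yv[test] - yv[test].mean(axis=0)) ** 2).sum(axis=0)
        defined = sst > 0
        if not defined.all():
            logger.info(
                "fold %d: %d feature(s) constant in held-out split; r2 undefined",
                k, int((~defined).sum()),
            )
        r2_folds[k, defined] = 1.0 - sse[defined] / sst[defined]
    mean_r2 = np.nanmean(r2_folds, axis=0)
    criticism = ModelCriticism(
        r2=mean_r2,
        folds=folds,
        threshold=threshold,
        kept=mean_r2 > threshold,
        feature_names=data.feature_names,
    )
    return criticism, pd.DataFrame(Z, index=Y.index, columns=Y.columns)
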