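"""Gamma/alpha/beta decomposition of pooled deviation patterns (ENDevs).

Pooling the per-subject c-deviant distributions psi_i with subject weights
w_i (default 1/N) gives a distribution over features for the whole cohort.
Three numbers equivalents decompose its heterogeneity at order q:

* gamma — effective number of c-deviant features in the pooled sample,
  ``Pi_q(sum_i w_i psi_i)``;
* alpha — effective number of c-deviant features per subject,
  ``( sum_i w_i^q sum_j psi_ij^q / sum_k w_k^q )^(1/(1-q))``,
  with the weighted-mean-entropy exponential as the q = 1 limit;
* beta = gamma / alpha — the *effective number of deviation patterns*
  (ENDevs): how many distinct, equally weighted ways the cohort deviates
  from the normative range.

beta is 1 when every subject deviates identically and N when the N subjects
deviate on disjoint feature sets with equal within-subject diversity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .deviance import DeviantPattern, deviant_patterns
from .errors import ValidationError
from .renyi import DEFAULT_ZERO_TOL, renyi_heterogeneity

__all__ = [
    "PooledSample",
    "HeterogeneityDecomposition",
    "pooled_distribution",
    "gamma_heterogeneity",
    "alpha_heterogeneity",
    "beta_heterogeneity",
    "endevs",
]


@dataclass(frozen=True)
class PooledSample:
    """N deviation patterns over a common feature set, with subject weights.

    Weights must be strictly positive; they are renormalized to sum to 1.
    """

    psi: np.ndarray
    weights: np.ndarray | None = None
    c: float | None = None
    mode: str | None = None

    def __post_init__(self):
        psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        n = psi.shape[0]
        if n == 0:
            raise ValidationError("pooled sample needs at least one pattern")
        if np.any(psi < 0):
            raise ValidationError("patterns must be nonnegative")
        sums = psi.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError("every pattern must sum to 1 within 1e-9")
        psi = psi / sums[:, None]
        w = self.weights
        w = np.full(n, 1.0 / n) if w is None else np.asarray(w, dtype=float).ravel()
        if w.shape != (n,):
            raise ValidationError("weights must have one entry per pattern")
        if np.any(w <= 0):
            raise ValidationError("weights must be strictly positive")
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "weights", w / w.sum())

    @classmethod
    def from_patterns(cls, patterns: list[DeviantPattern], weights=None) -> "PooledSample":
        """Stack DeviantPatterns; mixed thresholds c are rejected."""
        if not patterns:
            raise ValidationError("no patterns supplied")
        cs = {p.c for p in patterns}
        if len(cs) != 1:
            raise ValidationError(f"patterns were built at mixed thresholds {sorted(cs)}")
        lens = {p.psi.size for p in patterns}
        if len(lens) != 1:
            raise ValidationError("patterns must share a common feature set")
        return cls(np.array([p.psi for p in patterns]), weights, c=cs.pop())

    @property
    def n_subjects(self) -> int:
        return self.psi.shape[0]

    @property
    def n_features(self) -> int:
        return self.psi.shape[1]


@dataclass(frozen=True)
class HeterogeneityDecomposition:
    """(gamma, alpha, beta) effective numbers at order q and threshold c."""

    gamma: float
    alpha: float
    beta: float
    q: float
    c: float | None = None
    mode: str | None = None
    n_subjects: int = 0
    n_features: int = 0

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "c": self.c,
            "mode": self.mode,
            "gamma": self.gamma,
            "alpha": self.alpha,
            "beta": self.beta,
            "N": self.n_subjects,
            "M": self.n_features,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def pooled_distribution(sample: PooledSample) -> np.ndarray:
    """Weighted mean of the subject patterns: the pooled c-deviant distribution."""
    return sample.weights @ sample.psi


def gamma_heterogeneity(sample: PooledSample, q) -> float:
    """Effective number of c-deviant features in the pooled sample."""
    return renyi_heterogeneity(pooled_distribution(sample), q)


def alpha_heterogeneity(sample: PooledSample, q, *, zero_tol: float = DEFAULT_ZERO_TOL) -> float:
    """Effective number of c-deviant features per subject (order ``q``).

    The q = 1 limit is ``exp(sum_i w_i H(psi_i))``; the q = inf limit is
    ``max_k w_k / max_{i,j} w_i psi_ij``.
    """
    w = sample.weights
    psi = sample.psi
    q = float(q)
    if math.isnan(q) or q < 0:
        raise ValidationError(f"order q must be >= 0, got {q}")
    if q == 0:
        richness = (psi > zero_tol).sum(axis=1).astype(float)
        return float(richness.sum() / len(richness))
    if math.isinf(q):
        return float(w.max() / (w[:, None] * psi).max())
    if q == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(psi > 0, psi * np.log(np.where(psi > 0, psi, 1.0)), 0.0)
        entropies = -plogp.sum(axis=1)
        return float(np.exp(w @ entropies))
    num = (w**q) @ (psi**q).sum(axis=1)
    den = (w**q).sum()
    return float((num / den) ** (1.0 / (1.0 - q)))


def beta_heterogeneity(sample: PooledSample, q) -> HeterogeneityDecomposition:
    """Full decomposition; ``beta = gamma / alpha`` is the ENDevs."""
    gamma = gamma_heterogeneity(sample, q)
    alpha = alpha_heterogeneity(sample, q)
    return HeterogeneityDecomposition(
        gamma=gamma,
        alpha=alpha,
        beta=gamma / alpha,
        q=float(q),
        c=sample.c,
        mode=sample.mode,
        n_subjects=sample.n_subjects,
        n_features=sample.n_features,
    )


def endevs(
    Z,
    mode: str = "absolute-top",
    c: float = 0.01,
    q: float = 1.0,
    weights=None,
    *,
    on_degenerate: str = "drop",
) -> HeterogeneityDecomposition:
    """One-call pipeline: deviance matrix -> selection -> thresholding -> decomposition.

    ``Z`` is a signed standardized-deviance matrix for signed modes, or any
    nonnegative deviance matrix for ``absolute-top``.
    """
    psi, kept = deviant_patterns(Z, mode, c, on_degenerate=on_degenerate)
    if weights is not None:
        weights = np.asarray(weights, dtype=float).ravel()[kept]
    sample = PooledSample(psi, weights, c=c, mode=mode)
    return beta_heterogeneity(sample, q)
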