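"""Standardized deviance and per-subject c-deviant feature distributions.

A normative model scores each subject i and feature j with a z-like
*standardized deviance*

    Z_ij = (y_ij - mu_j(x_i)) / sqrt(sigma2_j(x_i) + eta2_j),

where mu and sigma2 are the predictive mean and variance at the subject's
covariates and eta2 is the feature's learned noise variance.  Keeping, for
each subject, only the features carrying the top 100c% of deviance
magnitudes and renormalizing yields the subject's *c-deviant feature
distribution* psi — a probability distribution describing *where* that
subject deviates from the normative range.  These per-subject patterns are
the raw material for the gamma/alpha/beta heterogeneity decomposition.

For models whose output is a matrix of Bernoulli parameters (e.g. an
autoencoder over binarized images), the squared Fisher-Hotelling-Rao
geodesic distance between predicted and observed pixel distributions stands
in for the squared standardized residual; see :func:`fhr_deviance`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateDevianceError,
    ThresholdError,
    ValidationError,
    ZeroVarianceError,
)
from .renyi import renyi_heterogeneity

logger = logging.getLogger(__name__)

#: Recognized extreme-value selection modes.  ``absolute-top`` ranks |Z|,
#: ``signed-top`` ranks raw Z (largest positive deviations), ``signed-bottom``
#: ranks -Z (largest negative deviations).  Pattern weights are always |Z| of
#: the selected entries.
SELECTION_MODES = ("absolute-top", "signed-top", "signed-bottom")


@dataclass(frozen=True)
class NormativePrediction:
    """Per-subject, per-feature normative predictions.

    Attributes
    ----------
    mu : (N, M) ndarray
        Predictive means, in feature units.
    sigma2 : (N, M) ndarray
        Predictive variances (epistemic part), feature units squared.
    eta2 : (M,) ndarray
        Learned per-feature noise variances.
    """

    mu: np.ndarray
    sigma2: np.ndarray
    eta2: np.ndarray

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        sigma2 = np.asarray(self.sigma2, dtype=float)
        eta2 = np.asarray(self.eta2, dtype=float).ravel()
        if mu.ndim != 2 or sigma2.shape != mu.shape:
            raise ValidationError("mu and sigma2 must be conforming N x M arrays")
        if eta2.shape != (mu.shape[1],):
            raise ValidationError("eta2 must have one entry per feature")
        if np.any(sigma2 < 0) or np.any(eta2 < 0):
            raise ValidationError("variances must be nonnegative")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma2", sigma2)
        object.__setattr__(self, "eta2", eta2)


@dataclass(frozen=True)
class DeviantPattern:
    """A subject's probability distribution over its c-deviant features."""

    psi: np.ndarray
    c: float
    support: np.ndarray = field(repr=False)

    def effective_number(self, q) -> float:
        """Effective number of c-deviant features at order ``q``."""
        return renyi_heterogeneity(self.psi, q)


def standardized_deviance(y, pred: NormativePrediction) -> np.ndarray:
    """Signed standardized-deviance matrix Z for observations ``y``.

    ``Z_ij = (y_ij - mu_ij) / sqrt(sigma2_ij + eta2_j)``.  Raises
    :class:`~endevs.errors.ZeroVarianceError` naming the offending feature(s)
    if any total variance is zero.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != pred.mu.shape:
        raise ValidationError(
            f"observations shape {y.shape} does not match predictions {pred.mu.shape}"
        )
    total_var = pred.sigma2 + pred.eta2[np.newaxis, :]
    if np.any(total_var <= 0):
        bad = np.unique(np.nonzero(total_var <= 0)[1])
        raise ZeroVarianceError(
            f"zero predictive-plus-noise variance for feature(s) {bad.tolist()}"
        )
    return (y - pred.mu) / np.sqrt(total_var)


def fhr_distance(p, y):
    """Fisher-Hotelling-Rao geodesic distance between Bernoulli distributions.

    ``2 * arccos(sqrt(p*y) + sqrt((1-p)*(1-y)))``, in radians; symmetric, zero
    iff ``p == y``, maximal (pi) for antipodal parameters 0 and 1.  Accepts
    scalars or broadcastable arrays with entries in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    for name, a in (("p", p), ("y", y)):
        if np.any(a < 0) or np.any(a > 1):
            raise ValidationError(f"{name} must lie in [0, 1]")
    inner = np.sqrt(p * y) + np.sqrt((1.0 - p) * (1.0 - y))
    d = 2.0 * np.arccos(np.clip(inner, -1.0, 1.0))
    return d if d.ndim else float(d)


def fhr_deviance(y, p) -> np.ndarray:
    """Elementwise squared FHR distance: an absolute deviance matrix in [0, pi^2].

    Used when the normative model emits Bernoulli parameters ``p`` for
    observations ``y`` in [0, 1]; the squared geodesic distance plays the role
    of the squared standardized residual.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    d = fhr_distance(p, y)
    return np.asarray(d) ** 2


def select_deviant(Z, mode: str = "absolute-top") -> np.ndarray:
    """Ranking matrix for extreme-value selection under ``mode``.

    Returns |Z| for ``absolute-top``, Z for ``signed-top`` (largest values
    rank first) and -Z for ``signed-bottom`` (most negative rank first).
    Downstream pattern weights always use |Z| of the selected entries.
    """
    Z = np.asarray(Z, dtype=float)
    if mode == "absolute-top":
        return np.abs(Z)
    if mode == "signed-top":
        return Z.copy()
    if mode == "signed-bottom":
        return -Z
    raise ValidationError(f"unknown selection mode {mode!r}; choose from {SELECTION_MODES}")


def c_deviant_distribution(z, c: float, *, magnitudes=None) -> DeviantPattern:
    """Build one subject's c-deviant feature distribution.

    Parameters
    ----------
    z : (M,) array-like
        Ranking values (nonnegative deviance magnitudes in the default
        absolute mode; possibly signed ranking scores for signed modes).
    c : float
        Extreme-value threshold in (0, 1]: features whose empirical survival
        fraction ``S(z_j) = #{k: z_k > z_j} / M`` is below ``c`` are retained.
        The maximum always survives (S = 0); ties survive or fall together.
    magnitudes : (M,) array-like, optional
        Nonnegative weights for the retained features; defaults to ``|z|``.

    Returns
    -------
    DeviantPattern
        ``psi`` sums to 1, is zero outside the retained support.
    """
    z = np.asarray(z, dtype=float).ravel()
    if not (0.0 < c <= 1.0):
        raise ThresholdError(f"threshold c must be in (0, 1], got {c}")
    if z.size == 0:
        raise DegenerateDevianceError("empty deviance vector")
    m = z.size
    mag = np.abs(z) if magnitudes is None else np.asarray(magnitudes, dtype=float).ravel()
    if mag.shape != z.shape or np.any(mag < 0):
        raise ValidationError("magnitudes must be nonnegative and match z in length")
    # empirical survival via sorted counts: S(v) = #{k: z_k > v} / M
    z_sorted = np.sort(z)
    survival = (m - np.searchsorted(z_sorted, z, side="right")) / m
    keep = survival < c
    weights = np.where(keep, mag, 0.0)
    total = weights.sum()
    if total <= 0:
        raise DegenerateDevianceError(
            "no positive deviance magnitude among retained features; "
            "subject has no deviation pattern"
        )
    return DeviantPattern(psi=weights / total, c=float(c), support=np.flatnonzero(keep))


def deviant_patterns(
    Z,
    mode: str = "absolute-top",
    c: float = 1.0,
    *,
    on_degenerate: str = "drop",
):
    """Per-subject c-deviant distributions for a whole deviance matrix.

    Rows with no positive magnitude carry no deviation pattern; with
    ``on_degenerate="drop"`` (default) they are removed with a logged warning,
    with ``"raise"`` they raise :class:`DegenerateDevianceError`.

    Returns
    -------
    psi : (N', M) ndarray
        One c-deviant distribution per retained subject.
    kept_rows : (N',) ndarray
        Indices of the retained rows of ``Z``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    ranks = select_deviant(Z, mode)
    mags = np.abs(Z)
    rows, kept = [], []
    for i in range(Z.shape[0]):
        try:
            pat = c_deviant_distribution(ranks[i], c, magnitudes=mags[i])
        except DegenerateDevianceError:
            if on_degenerate == "raise":
                raise
            continue
        rows.append(pat.psi)
        kept.append(i)
    n_dropped = Z.shape[0] - len(kept)
    if n_dropped:
        logger.warning("dropped %d subject(s) with no deviation pattern", n_dropped)
    if not rows:
        raise DegenerateDevianceError("every subject row was degenerate")
    return np.array(rows), np.array(kept)


def per_subject_effective(pattern: DeviantPattern, q) -> float:
    """Effective number of c-deviant features for one subject (order ``q``)."""
    return pattern.effective_number(q)
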