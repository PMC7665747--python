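"""Renyi heterogeneity: the numbers equivalent (Hill number) of a distribution.

For a discrete probability distribution ``p`` over ``n`` categories, the
order-``q`` Renyi heterogeneity is

.. math::

    \\Pi_q(p) = \\Big(\\sum_i p_i^q\\Big)^{1/(1-q)},

with the standard limits: the support size at ``q = 0``, the exponential of
the Shannon entropy (natural log) at ``q = 1``, and ``1 / max_i p_i`` at
``q = inf``.  The result is an *effective number of categories*: the size of
a uniform distribution with the same diversity.  Unlike variance or raw
entropies it scales linearly — replicating a system k-fold multiplies the
heterogeneity by exactly k (the replication principle) — which is what makes
it suitable as a heterogeneity unit.

The order ``q`` controls sensitivity to rare categories: low ``q`` counts
every category that carries any mass, high ``q`` is dominated by the most
probable ones.

For a continuous density the same construction gives an effective volume;
only the Gaussian closed form is provided here (it is what the package's
illustrations and tests need).
"""

from __future__ import annotations

import math

import numpy as np

from .errors import (
    DegenerateDistributionError,
    UnsupportedOrderError,
    ValidationError,
)

#: Probabilities at or below this value are treated as structural zeros when
#: counting support at q = 0 (configurable per call).
DEFAULT_ZERO_TOL = 1e-12

#: Maximum tolerated deviation of sum(p) from 1 before the input is rejected
#: rather than silently renormalized.
SUM_TOL = 1e-9


def validate_distribution(p, *, sum_tol: float = SUM_TOL) -> np.ndarray:
    """Validate and return ``p`` as a probability vector.

    Entries must be nonnegative and sum to 1 within ``sum_tol``; inputs within
    tolerance are renormalized exactly, larger deviations raise
    :class:`~endevs.errors.ValidationError`.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0 or not np.any(p > 0):
        raise DegenerateDistributionError(
            "distribution is empty or carries no probability mass"
        )
    if np.any(p < 0):
        raise ValidationError("distribution has negative entries")
    if not np.all(np.isfinite(p)):
        raise ValidationError("distribution has non-finite entries")
    total = p.sum()
    if abs(total - 1.0) > sum_tol:
        raise ValidationError(
            f"distribution sums to {total!r}, more than {sum_tol} away from 1"
        )
    return p / total


def _validate_order(q) -> float:
    q = float(q)
    if math.isnan(q) or q < 0:
        raise UnsupportedOrderError(f"order q must be >= 0, got {q}")
    return q


def renyi_heterogeneity(p, q, *, zero_tol: float = DEFAULT_ZERO_TOL) -> float:
    """Order-``q`` Renyi heterogeneity (numbers equivalent) of ``p``.

    Parameters
    ----------
    p : array-like
        Probability vector (nonnegative, sums to 1 within ``1e-9``).
    q : float
        Order, ``q >= 0``; ``numpy.inf`` is accepted.
    zero_tol : float
        Entries at or below this are excluded from the support count at
        ``q = 0``.

    Returns
    -------
    float
        Effective number of categories, ``>= 1`` for any valid ``p``.
    """
    p = validate_distribution(p)
    q = _validate_order(q)
    if q == 0:
        return float(np.count_nonzero(p > zero_tol))
    if math.isinf(q):
        return float(1.0 / p.max())
    pos = p[p > 0]
    if q == 1:
        return float(np.exp(-np.sum(pos * np.log(pos))))
    return float(np.sum(pos**q) ** (1.0 / (1.0 - q)))


def shannon_entropy(p) -> float:
    """Shannon entropy (natural log) of ``p``; zero entries contribute nothing."""
    p = validate_distribution(p)
    pos = p[p > 0]
    return float(-np.sum(pos * np.log(pos)))


def gaussian_heterogeneity(sigma: float, q, *, mu: float = 0.0) -> float:
    """Renyi heterogeneity of a univariate Gaussian: an effective length.

    Closed form ``sigma * sqrt(2*pi) * q**(1/(2*(q-1)))`` for ``q not in
    {0, 1}``, with the limit ``sigma * sqrt(2*pi*e)`` at ``q = 1`` and
    ``sigma * sqrt(2*pi)`` at ``q = inf``.  Linear in ``sigma``; the mean is
    irrelevant (translation invariance) and accepted only for interface
    symmetry.

    ``q = 0`` diverges (a Gaussian has unbounded support) and raises
    :class:`~endevs.errors.UnsupportedOrderError`.
    """
    del mu  # translation invariant
    sigma = float(sigma)
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    q = _validate_order(q)
    if q == 0:
        raise UnsupportedOrderError(
            "q = 0 heterogeneity of a Gaussian diverges: the support is unbounded"
        )
    if q == 1:
        return sigma * math.sqrt(2.0 * math.pi * math.e)
    if math.isinf(q):
        return sigma * math.sqrt(2.0 * math.pi)
    return sigma * math.sqrt(2.0 * math.pi) * q ** (1.0 / (2.0 * (q - 1.0)))
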