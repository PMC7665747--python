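"""Bootstrap confidence intervals and heterogeneity accumulation curves.

ENDevs is a plug-in estimate from a finite cohort; uncertainty is quantified
by resampling subjects with replacement, rebuilding the deviation patterns
in each replicate, and taking percentile (2.5/97.5) intervals over the
replicate beta values.  Accumulation curves re-estimate ENDevs at a grid of
subsample sizes: if a cohort deviates in only a few coherent ways the curve
plateaus early; if new subjects keep contributing novel deviation patterns
it keeps rising.

Thresholding is a per-subject operation here, so each subject's pattern is
computed once up front and replicates simply reindex the pattern matrix;
subjects with no positive deviance are dropped (with a logged warning)
before any resampling.

Seeding: each (root seed, sample size) pair owns an independent
``SeedSequence`` which spawns one substream per replicate, so results are
bit-reproducible, replicates are independent, and the accumulation curve at
n = N coincides exactly with the full-sample bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import PooledSample, beta_heterogeneity
from .deviance import deviant_patterns
from .errors import ValidationError
from .renyi import DEFAULT_ZERO_TOL

__all__ = ["BootstrapResult", "AccumulationCurve", "bootstrap_endevs", "accumulation_curve"]


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap mean and 95% percentile interval for ENDevs."""

    mean: float
    ci_low: float
    ci_high: float
    B: int
    seed: int
    q: float
    c: float
    mode: str
    n: int
    point_estimate: float
    replicates: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class AccumulationCurve:
    """ENDevs re-estimated at increasing subsample sizes."""

    sizes: tuple
    results: tuple

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per subsample size."""
        return pd.DataFrame(
            {
                "mode": [r.mode for r in self.results],
                "c": [r.c for r in self.results],
                "q": [r.q for r in self.results],
                "n": list(self.sizes),
                "mean": [r.mean for r in self.results],
                "ci_low": [r.ci_low for r in self.results],
                "ci_high": [r.ci_high for r in self.results],
                "B": [r.B for r in self.results],
                "seed": [r.seed for r in self.results],
            }
        )


def _beta_equal_weights(psi: np.ndarray, q: float) -> float:
    """beta = gamma / alpha for a pattern matrix with equal subject weights.

    Fast path used inside bootstrap loops; identical to
    ``beta_heterogeneity(PooledSample(psi), q).beta``.
    """
    n = psi.shape[0]
    pooled = psi.mean(axis=0)
    qf = float(q)
    # gamma
    if qf == 0:
        gamma = float(np.count_nonzero(pooled > DEFAULT_ZERO_TOL))
        alpha = float((psi > DEFAULT_ZERO_TOL).sum(axis=1).mean())
    elif math.isinf(qf):
        gamma = 1.0 / pooled.max()
        alpha = 1.0 / psi.max()
    elif qf == 1:
        pos = pooled[pooled > 0]
        gamma = float(np.exp(-np.sum(pos * np.log(pos))))
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(psi > 0, psi * np.log(np.where(psi > 0, psi, 1.0)), 0.0)
        alpha = float(np.exp(-plogp.sum(axis=1).mean()))
    else:
        pos = pooled[pooled > 0]
        gamma = float(np.sum(pos**qf) ** (1.0 / (1.0 - qf)))
        alpha = float(((psi**qf).sum(axis=1).mean()) ** (1.0 / (1.0 - qf)))
    return gamma / alpha


def _replicate_betas(psi, size, q, B, seed, replace):
    n = psi.shape[0]
    children = np.random.SeedSequence([int(seed), int(size)]).spawn(B)
    betas = np.empty(B)
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        if replace:
            idx = rng.integers(0, n, size=size)
        else:
            idx = rng.permutation(n)[:size]
        betas[b] = _beta_equal_weights(psi[idx], q)
    return betas


def bootstrap_endevs(
    Z,
    mode: str = "absolute-top",
    c: float = 0.01,
    q: float = 1.0,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap mean and 95% CI for ENDevs of deviance matrix ``Z``.

    Subjects are resampled with replacement ``B`` times; each replicate
    reweights its (possibly duplicated) subjects equally at 1/N and records
    the beta heterogeneity.  Identical seeds give identical output, and
    increasing ``B`` extends rather than reshuffles the replicate stream.
    """
    if B < 1:
        raise ValidationError(f"B must be >= 1, got {B}")
    psi, _ = deviant_patterns(Z, mode, c)
    n = psi.shape[0]
    if n < 2:
        raise ValidationError("bootstrap needs at least 2 non-degenerate subjects")
    point = beta_heterogeneity(PooledSample(psi, c=c, mode=mode), q).beta
    betas = _replicate_betas(psi, n, q, B, seed, replace=True)
    lo, hi = np.percentile(betas, [2.5, 97.5])
    return BootstrapResult(
        mean=float(betas.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        B=B,
        seed=int(seed),
        q=float(q),
        c=float(c),
        mode=mode,
        n=n,
        point_estimate=float(point),
        replicates=betas,
    )


def accumulation_curve(
    Z,
    mode: str = "absolute-top",
    c: float = 0.01,
    q: float = 1.0,
    sizes=None,
    B: int = 1000,
    seed: int = 0,
    *,
    replace: bool = True,
) -> AccumulationCurve:
    """ENDevs bootstrap estimates at a grid of subsample sizes.

    ``sizes`` defaults to ``5, 15, 25, ... <= N``.  Subsamples are drawn with
    replacement by default (matching the bootstrap convention, so the curve
    at n = N equals :func:`bootstrap_endevs`); ``replace=False`` gives
    rarefaction-style subsampling without replacement.
    """
    psi, _ = deviant_patterns(Z, mode, c)
    n = psi.shape[0]
    if sizes is None:
        sizes = list(range(5, n + 1, 10))
    sizes = [int(s) for s in sizes]
    if not sizes:
        raise ValidationError("sizes grid is empty")
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValidationError("sizes must be strictly increasing")
    if sizes[0] < 2 or sizes[-1] > n:
        raise ValidationError(f"sizes must lie in [2, {n}]")
    results = []
    for size in sizes:
        betas = _replicate_betas(psi, size, q, B, seed, replace)
        lo, hi = np.percentile(betas, [2.5, 97.5])
        results.append(
            BootstrapResult(
                mean=float(betas.mean()),
                ci_low=float(lo),
                ci_high=float(hi),
                B=B,
                seed=int(seed),
                q=float(q),
                c=float(c),
                mode=mode,
                n=size,
                point_estimate=float(_beta_equal_weights(psi, q)),
                replicates=betas,
            )
        )
    return AccumulationCurve(sizes=tuple(sizes), results=tuple(results))
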