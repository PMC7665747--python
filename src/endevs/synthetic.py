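"""Synthetic study systems: a nonlinear covariate-to-feature generator and a
multi-class template fixture.

The main generator produces M real-valued features per subject — analogous
to M regional brain measures — from five covariates x = (x1..x5):

    y_j = (x1 - 2) sin(x2 pi t_j) cos(x3 pi t_j) - cos(pi (t_j - x4)) + eps_j,
    eps_j ~ Normal(x5, noise_sd),

on an evenly spaced grid t of M points over [-2, 2].  Covariates are drawn
from group-specific diagonal Gaussians.  The "normative" and "unaffected"
groups share one covariate distribution; the "affected" group shifts the
amplitude covariate x1 (+2.5) and frequency covariate x2 (+0.5) of the
product term, producing a coherent, multi-feature displacement of the
response curves — concentrated where |sin(x2 pi t) cos(x3 pi t)| is large —
rather than a shift along a single feature.  That coherence is what the
ENDevs measure is designed to detect: affected subjects deviate from the
normative range in similar ways, so their effective number of deviation
patterns is low.

A second generator builds a small multi-class fixture — each class a sparse
template of Bernoulli parameters plus bounded noise — emulating image-class
data for the Fisher-Hotelling-Rao deviance route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "ClassFixture",
    "feature_grid",
    "mean_curve",
    "generate_subject",
    "generate_cohort",
    "generate_class_fixture",
]

GROUPS = ("normative", "unaffected", "affected")


def _default_means():
    return {
        "normative": (0.0, 0.0, 0.0, 0.0, 0.0),
        "unaffected": (0.0, 0.0, 0.0, 0.0, 0.0),
        # amplitude (x1) and frequency (x2) of the product term shifted:
        # all affected subjects deviate coherently at the high-|t| features
        "affected": (2.5, 0.5, 0.0, 0.0, 0.0),
    }


def _default_sds():
    # x2, x3 drive the sin/cos frequencies; their spread is kept small enough
    # that the covariate-to-feature map stays resolvable from N = 50 subjects
    sds = (1.0, 0.3, 0.3, 1.0, 1.0)
    return {g: sds for g in GROUPS}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic covariate-shift system.

    ``n_features`` features on an even grid over [``lower``, ``upper``];
    residual noise has sd ``noise_sd`` and a mean given by covariate x5.
    Covariate means/sds are per group; all values are dimensionless.
    """

    n_features: int = 30
    lower: float = -2.0
    upper: float = 2.0
    noise_sd: float = 0.1
    n_subjects: int = 50
    covariate_means: dict = field(default_factory=_default_means)
    covariate_sds: dict = field(default_factory=_default_sds)

    def __post_init__(self):
        if self.n_features < 2:
            raise ValidationError("need at least 2 features for a grid")
        if self.upper <= self.lower:
            raise ValidationError("upper grid bound must exceed lower")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        for g, sds in self.covariate_sds.items():
            if any(s <= 0 for s in sds):
                raise ValidationError(f"covariate sds for group {g!r} must be > 0")


@dataclass
class SyntheticCohort:
    """One generated group: covariates X (N x 5) and features Y (N x M)."""

    X: pd.DataFrame
    Y: pd.DataFrame
    group: str
    seed: int | None = None


def feature_grid(cfg: SyntheticConfig) -> np.ndarray:
    """Evenly spaced grid t_j = (j-1)(u-l)/(M-1) + l, j = 1..M."""
    m = cfg.n_features
    return np.arange(m) * (cfg.upper - cfg.lower) / (m - 1) + cfg.lower


def mean_curve(x, cfg: SyntheticConfig) -> np.ndarray:
    """Noise-free part of the feature vector for covariates ``x`` (length 5)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != 5:
        raise ValidationError("expected 5 covariates")
    t = feature_grid(cfg)
    return (x[0] - 2.0) * np.sin(x[1] * np.pi * t) * np.cos(x[2] * np.pi * t) - np.cos(
        np.pi * (t - x[3])
    )


def generate_subject(x, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """One subject's features: mean curve plus Normal(x5, noise_sd) residuals."""
    x = np.asarray(x, dtype=float).ravel()
    return mean_curve(x, cfg) + rng.normal(x[4], cfg.noise_sd, size=cfg.n_features)


def generate_cohort(
    cfg: SyntheticConfig, group: str, seed: int | None = None, rng: np.random.Generator | None = None
) -> SyntheticCohort:
    """Draw a cohort for ``group``: covariates from its diagonal Gaussian, then features."""
    if group not in cfg.covariate_means:
        raise ValidationError(
            f"unknown group {group!r}; configured groups: {sorted(cfg.covariate_means)}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    means = np.asarray(cfg.covariate_means[group], dtype=float)
    sds = np.asarray(cfg.covariate_sds[group], dtype=float)
    n = cfg.n_subjects
    X = means + sds * rng.standard_normal((n, 5))
    Y = np.array([generate_subject(x, cfg, rng) for x in X])
    ids = [f"{group}-{i:03d}" for i in range(n)]
    xcols = [f"x{k}" for k in range(1, 6)]
    ycols = [f"f{j:02d}" for j in range(1, cfg.n_features + 1)]
    return SyntheticCohort(
        X=pd.DataFrame(X, index=ids, columns=xcols),
        Y=pd.DataFrame(Y, index=ids, columns=ycols),
        group=group,
        seed=seed,
    )


@dataclass
class ClassFixture:
    """Class templates (K x M Bernoulli parameters) and noisy observations (K x N x M)."""

    templates: np.ndarray
    observations: np.ndarray
    seed: int

    @property
    def n_classes(self) -> int:
        return self.templates.shape[0]


def generate_class_fixture(
    n_classes: int = 3,
    n_per_class: int = 40,
    n_features: int = 96,
    seed: int = 0,
    *,
    background: float = 0.1,
    signal: float = 0.85,
    noise_sd: float = 0.05,
) -> ClassFixture:
    """Multi-class fixture with distinct sparse templates plus bounded noise.

    Each class activates a disjoint block of features at level ``signal``
    over a ``background`` floor; observations add Gaussian noise and are
    clipped into (0, 1), making them valid inputs for
    :func:`endevs.deviance.fhr_deviance`.  Within-class observations are
    closer (in FHR distance) to their own template than to any other class's
    template by construction.
    """
    if n_classes < 2:
        raise ValidationError("need at least 2 classes")
    block = n_features // (2 * n_classes)
    if block < 1:
        raise ValidationError(
            f"{n_features} features are too few for {n_classes} disjoint templates"
        )
    rng = np.random.default_rng(seed)
    templates = np.full((n_classes, n_features), background)
    stride = n_features // n_classes
    for k in range(n_classes):
        templates[k, k * stride : k * stride + block] = signal
    obs = np.clip(
        templates[:, None, :] + rng.normal(0.0, noise_sd, (n_classes, n_per_class, n_features)),
        0.01,
        0.99,
    )
    return ClassFixture(templates=templates, observations=obs, seed=seed)
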