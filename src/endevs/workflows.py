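"""End-to-end study pipelines chaining the normative, deviance, decomposition
and resampling stages.

These are the functions the command-line interface, the examples and the
reproduction script call: each takes plain tables (or a seed for the
synthetic generators) and returns tidy DataFrames with one row per
(group, mode, c, q) cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decomposition import endevs
from .deviance import fhr_deviance, standardized_deviance
from .normative import NormativeModel, criticize
from .resampling import accumulation_curve, bootstrap_endevs
from .synthetic import ClassFixture, SyntheticConfig, generate_class_fixture, generate_cohort

__all__ = [
    "derive_seeds",
    "synthetic_group_betas",
    "class_fixture_betas",
    "endevs_table",
    "normative_endevs_study",
    "group_accumulation_curves",
]


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from a root seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def synthetic_group_betas(
    seed: int,
    cfg: SyntheticConfig | None = None,
    c_values=(0.01, 0.05, 0.3, 1.0),
    q: float = 1.0,
    B: int = 200,
    backend: str = "gp",
    mode: str = "absolute-top",
) -> pd.DataFrame:
    """Full synthetic experiment for one seed.

    Generates a normative cohort, fits the normative model on it, scores an
    independent unaffected cohort (same covariate distribution) and an
    affected cohort (shifted covariates), then bootstraps ENDevs per group
    and threshold.  Groups reported: ``unaffected``, ``affected`` and their
    union ``pooled``.

    Returns a tidy frame with columns
    ``group, mode, c, q, n, mean, ci_low, ci_high, point, B, seed``.
    """
    cfg = cfg or SyntheticConfig()
    s_norm, s_unaff, s_aff, s_boot = derive_seeds(seed, 4)
    normative = generate_cohort(cfg, "normative", seed=s_norm)
    unaffected = generate_cohort(cfg, "unaffected", seed=s_unaff)
    affected = generate_cohort(cfg, "affected", seed=s_aff)

    model = NormativeModel(backend=backend, random_state=s_norm).fit(normative.X, normative.Y)
    z_by_group = {}
    for cohort in (unaffected, affected):
        pred = model.predict(cohort.X)
        z_by_group[cohort.group] = standardized_deviance(cohort.Y.to_numpy(), pred)
    z_by_group["pooled"] = np.vstack([z_by_group["unaffected"], z_by_group["affected"]])
    return endevs_table(z_by_group, modes=(mode,), c_values=c_values, q=q, B=B, seed=s_boot)


def class_fixture_betas(
    seed: int = 0,
    n_classes: int = 3,
    n_per_class: int = 40,
    n_features: int = 96,
    c_values=(0.01, 0.02, 0.05, 0.1),
    q: float = 1.0,
    fixture: ClassFixture | None = None,
) -> pd.DataFrame:
    """ENDevs for every (normative class, target class, c) combination.

    The normative model of class k is its Bernoulli template; deviance of a
    target cohort is the squared Fisher-Hotelling-Rao distance to that
    template.  Columns: ``normative_class, target_class, c, q, beta``.
    """
    fx = fixture or generate_class_fixture(n_classes, n_per_class, n_features, seed)
    rows = []
    for k in range(fx.n_classes):
        template = np.tile(fx.templates[k], (fx.observations.shape[1], 1))
        for j in range(fx.n_classes):
            z_abs = fhr_deviance(fx.observations[j], template)
            for c in c_values:
                dec = endevs(z_abs, mode="absolute-top", c=c, q=q)
                rows.append(
                    {
                        "normative_class": k,
                        "target_class": j,
                        "c": c,
                        "q": q,
                        "beta": dec.beta,
                        "gamma": dec.gamma,
                        "alpha": dec.alpha,
                    }
                )
    return pd.DataFrame(rows)


def endevs_table(
    z_by_group: dict,
    modes=("absolute-top",),
    c_values=(0.01, 0.02, 0.03, 0.05, 0.07),
    q: float = 1.0,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap ENDevs table over groups x selection modes x thresholds.

    ``z_by_group`` maps group label to a signed deviance matrix.  This is the
    tabulation used for cohort comparisons: one row per cell, with bootstrap
    mean, 95% CI and the full-sample point estimate.
    """
    rows = []
    for group, Z in z_by_group.items():
        for mode in modes:
            for c in c_values:
                res = bootstrap_endevs(Z, mode=mode, c=c, q=q, B=B, seed=seed)
                rows.append(
                    {
                        "group": group,
                        "mode": mode,
                        "c": c,
                        "q": q,
                        "n": res.n,
                        "mean": res.mean,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "point": res.point_estimate,
                        "B": B,
                        "seed": res.seed,
                    }
                )
    return pd.DataFrame(rows)


def normative_endevs_study(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    groups,
    normative_label,
    schema: dict | None = None,
    folds: int = 10,
    threshold: float = 0.2,
    backend: str = "gp",
    modes=("absolute-top", "signed-bottom", "signed-top"),
    c_values=(0.01, 0.02, 0.03, 0.05, 0.07),
    q: float = 1.0,
    B: int = 1000,
    seed: int = 0,
):
    """Cohort-comparison study on real tables: the full normative workflow.

    1. Cross-validated criticism on the normative subgroup; features with
       mean held-out r^2 <= ``threshold`` are dropped.  The concatenated
       out-of-fold deviances are the normative group's deviation profiles.
    2. The model is refit on the whole normative subgroup (kept features
       only) and used to score every clinical subgroup.
    3. Bootstrap ENDevs per (group, mode, c).

    Returns ``(criticism, table)`` where ``table`` is the tidy frame from
    :func:`endevs_table`.
    """
    X = pd.DataFrame(X)
    Y = pd.DataFrame(Y)
    groups = pd.Series(np.asarray(groups), index=Y.index)
    labels = groups.unique().tolist()
    if normative_label not in labels:
        raise ValueError(f"normative label {normative_label!r} not among groups {labels}")
    is_norm = groups == normative_label
    crit, z_norm = criticize(
        X[is_norm], Y[is_norm], schema=schema, folds=folds,
        threshold=threshold, backend=backend, seed=seed,
    )
    kept_cols = [f for f, k in zip(crit.feature_names, crit.kept) if k]
    if not kept_cols:
        raise ValueError("no feature passed the explained-variance filter")
    model = NormativeModel(backend=backend, schema=schema, random_state=seed).fit(
        X[is_norm], Y.loc[is_norm, kept_cols]
    )
    z_by_group = {str(normative_label): z_norm[kept_cols].to_numpy()}
    for label in labels:
        if label == normative_label:
            continue
        sel = groups == label
        pred = model.predict(X[sel])
        z_by_group[str(label)] = standardized_deviance(
            Y.loc[sel, kept_cols].to_numpy(), pred
        )
    table = endevs_table(z_by_group, modes=modes, c_values=c_values, q=q, B=B, seed=seed)
    return crit, table


def group_accumulation_curves(
    z_by_group: dict,
    mode: str = "absolute-top",
    c: float = 0.01,
    q: float = 1.0,
    sizes=None,
    B: int = 1000,
    seed: int = 0,
    replace: bool = True,
) -> pd.DataFrame:
    """Heterogeneity accumulation curves for several groups, as one tidy frame."""
    frames = []
    for group, Z in z_by_group.items():
        curve = accumulation_curve(
            Z, mode=mode, c=c, q=q, sizes=sizes, B=B, seed=seed, replace=replace
        )
        frame = curve.to_frame()
        frame.insert(0, "group", group)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
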