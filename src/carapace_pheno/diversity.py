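"""Phenotypic diversity in a multidimensional phenotypic space (MDPS).

Each crab is a point in a six-dimensional space of appearance metrics
(hue, saturation, brightness, marking size, total energy, proportion
energy).  Every metric is first standardized as a proportion of its
maximum over the *entire* dataset so all axes run 0–1.  Diversity of a
group (a site × life-stage dataset) is then the mean, over individuals,
of each individual's mean Euclidean distance to every other member of its
group — larger values mean crabs are more spread out in phenotype space.

Because more individuals can inflate apparent diversity, a resampling
control repeatedly (99 times by default) draws random subsamples of the
size of the smallest group in a comparison, without replacement, and
reports the mean and standard deviation of the subsampled MDPS values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PHENOTYPE_METRICS",
    "MDPSResult",
    "standardize",
    "mdps",
    "resample_mdps",
]

#: The six appearance metrics spanning the phenotypic space.
PHENOTYPE_METRICS = (
    "hue",
    "saturation",
    "brightness",
    "marking_size",
    "total_energy",
    "proportion_energy",
)


@dataclass
class MDPSResult:
    """Per-group diversity values, with optional resampling summary."""

    table: pd.DataFrame  # one row per group
    individual_means: pd.Series  # indexed like the input rows
    metric_cols: tuple[str, ...]
    group_cols: tuple[str, ...]
    reps: int | None = None
    subsample_n: int | None = None
    seed: int | None = None


def standardize(
    cohort: pd.DataFrame, metric_cols: tuple[str, ...] = PHENOTYPE_METRICS
) -> pd.DataFrame:
    """Scale each metric by its maximum over the whole dataset.

    The divisor is the dataset-wide maximum (never a per-group maximum),
    so groups remain comparable.  Idempotent: the maximum of a
    standardized column is 1.
    """
    out = cohort.copy()
    for col in metric_cols:
        m = out[col].max()
        if not np.isfinite(m) or m <= 0:
            raise ValueError(f"column {col!r}: maximum must be positive to standardize")
        out[col] = out[col] / m
    return out


def _group_mdps(x: np.ndarray) -> tuple[float, np.ndarray]:
    """Group MDPS and per-individual mean pairwise distances (brute pdist)."""
    n = x.shape[0]
    d = squareform(pdist(x, metric="euclidean"))
    indiv = d.sum(axis=1) / (n - 1)
    return float(indiv.mean()), indiv


def mdps(
    cohort: pd.DataFrame,
    group_cols: tuple[str, ...] = ("site", "stage"),
    metric_cols: tuple[str, ...] = PHENOTYPE_METRICS,
) -> MDPSResult:
    """Mean pairwise phenotypic distance per group.

    ``cohort`` should already be standardized (see :func:`standardize`).
    Groups of size 1 have undefined diversity and are reported as NaN.
    """
    group_cols = tuple(group_cols)
    rows = []
    indiv = pd.Series(np.nan, index=cohort.index, name="individual_mdps")
    for key, sub in cohort.groupby(list(group_cols), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(sub)
        if n < 2:
            rows.append(dict(zip(group_cols, key), n=n, mdps=np.nan))
            continue
        value, per = _group_mdps(sub[list(metric_cols)].to_numpy(dtype=float))
        indiv.loc[sub.index] = per
        rows.append(dict(zip(group_cols, key), n=n, mdps=value))
    return MDPSResult(
        table=pd.DataFrame(rows),
        individual_means=indiv,
        metric_cols=tuple(metric_cols),
        group_cols=group_cols,
    )


def resample_mdps(
    cohort: pd.DataFrame,
    group_cols: tuple[str, ...] = ("site", "stage"),
    metric_cols: tuple[str, ...] = PHENOTYPE_METRICS,
    subsample_n: int | None = None,
    reps: int = 99,
    seed: int | None = None,
) -> MDPSResult:
    """Sample-size-controlled MDPS via repeated subsampling.

    For every group, draw ``reps`` random subsamples of ``subsample_n``
    individuals without replacement and average the resulting MDPS values.
    ``subsample_n`` defaults to the smallest group size in the comparison.
    When ``subsample_n`` equals a group's size every resample is the full
    group, so the resampled mean equals the full MDPS and the SD is 0.
    """
    group_cols = tuple(group_cols)
    full = mdps(cohort, group_cols, metric_cols)
    sizes = full.table["n"]
    if subsample_n is None:
        subsample_n = int(sizes.min())
    if subsample_n < 2:
        raise ValueError("subsample_n must be at least 2")
    if subsample_n > sizes.max():
        raise ValueError("subsample_n exceeds every group size")
    rng = np.random.default_rng(seed)
    res_mean, res_sd = [], []
    for _, row in full.table.iterrows():
        key = tuple(row[c] for c in group_cols)
        sub = cohort
        for c, v in zip(group_cols, key):
            sub = sub[sub[c] == v]
        n = len(sub)
        if subsample_n > n:
            raise ValueError(
                f"group {key}: subsample_n={subsample_n} exceeds group size {n}"
            )
        x = sub[list(metric_cols)].to_numpy(dtype=float)
        vals = np.empty(reps)
        for r in range(reps):
            idx = rng.choice(n, size=subsample_n, replace=False)
            vals[r], _ = _group_mdps(x[idx])
        res_mean.append(float(vals.mean()))
        res_sd.append(float(vals.std(ddof=1)) if reps > 1 else 0.0)
    table = full.table.copy()
    table["resampled_mean"] = res_mean
    table["resampled_sd"] = res_sd
    table["subsample_n"] = subsample_n
    table["reps"] = reps
    table["is_reference_group"] = table["n"] == subsample_n
    return MDPSResult(
        table=table,
        individual_means=full.individual_means,
        metric_cols=tuple(metric_cols),
        group_cols=group_cols,
        reps=reps,
        subsample_n=subsample_n,
        seed=seed,
    )
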