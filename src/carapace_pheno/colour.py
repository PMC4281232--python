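"""Colour metrics from four-channel carapace reflectances.

A crab's carapace colour is summarised from its mean reflectance in four
camera channels — longwave (LW, red), mediumwave (MW, green), shortwave
(SW, blue) and ultraviolet (UV) — on the calibrated 0–255 scale where 255
is 100% reflectance.  Four metrics are derived:

* **brightness** — the plain mean ``(LW + MW + SW + UV) / 4``, overall
  reflectance across the spectrum without assuming any receiver's vision;
* **saturation** — distance from the achromatic centre of a tetrahedral
  colour space whose vertices represent exclusive stimulation of one
  channel, computed on brightness-normalised channel proportions;
* **hue 1** — ``UV / ((LW + MW + SW) / 3)``, the relative UV reflectance;
* **hue 2** — ``(LW + UV) / (MW + SW)``, an opponent-style ratio of
  red/brown-plus-UV against blue-green.  Equal channels give exactly 1,
  the achromatic point, for both hue ratios.

A PCA screen over cohort channel proportions and a pairwise correlation
screen are provided as the diagnostics used to justify retaining
brightness, saturation and hue 2 (hue 1 correlates with saturation and is
dropped from downstream statistics by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ChannelQuad",
    "ProportionQuad",
    "ColourMetrics",
    "TETRA_VERTEX_DISTANCE",
    "tetra_vertices",
    "brightness",
    "proportions",
    "tetra_saturation",
    "hues",
    "compute_colour_metrics",
    "pca_colour_screen",
    "correlation_screen",
]

#: Channel order used throughout the package.
CHANNELS = ("lw", "mw", "sw", "uv")

#: Distance of each tetrahedron vertex from the achromatic origin.
TETRA_VERTEX_DISTANCE = 0.75


@dataclass(frozen=True)
class ChannelQuad:
    """Mean LW/MW/SW/UV reflectances over a carapace ROI (0–255 scale)."""

    lw: float
    mw: float
    sw: float
    uv: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("channel means must be finite")
        if np.any(vals < 0):
            raise ValueError("channel means must be non-negative")
        if np.all(vals == 0):
            raise ValueError("all-zero channel quad")

    def as_array(self) -> np.ndarray:
        return np.array([self.lw, self.mw, self.sw, self.uv], dtype=float)

    def scaled(self, k: float) -> "ChannelQuad":
        return ChannelQuad(self.lw * k, self.mw * k, self.sw * k, self.uv * k)


@dataclass(frozen=True)
class ProportionQuad:
    """Channel proportions (each channel / channel sum); sum to 1."""

    lw: float
    mw: float
    sw: float
    uv: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {vals.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lw, self.mw, self.sw, self.uv], dtype=float)


@dataclass(frozen=True)
class ColourMetrics:
    brightness: float
    saturation: float
    hue1: float
    hue2: float


def tetra_vertices(vertex_distance: float = TETRA_VERTEX_DISTANCE) -> np.ndarray:
    """Vertices of the regular colour tetrahedron, rows ordered (UV, SW, MW, LW).

    Centred on the origin (the achromatic point) with every vertex at
    ``vertex_distance`` from it.  Any regular tetrahedron gives saturations
    identical up to a global constant; this convention pins the constant.
    """
    base = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    return vertex_distance * base / np.sqrt(3.0)


def brightness(q: ChannelQuad) -> float:
    """Overall reflectance, (LW + MW + SW + UV) / 4."""
    return float(q.as_array().mean())


def proportions(q: ChannelQuad) -> ProportionQuad:
    """Standardise a quad to proportions of the channel total.

    Removes absolute brightness so that saturation and the PCA screen see
    only relative spectral shape.
    """
    vals = q.as_array()
    total = vals.sum()
    if total <= 0:
        raise ValueError("cannot form proportions of an all-zero quad")
    p = vals / total
    return ProportionQuad(*p)


def tetra_saturation(
    p: ProportionQuad, vertex_distance: float = TETRA_VERTEX_DISTANCE
) -> float:
    """Distance from the achromatic centre of the tetrahedral colour space.

    The colour's position is the proportion-weighted sum of the four
    vertices; equal proportions land exactly on the origin (saturation 0)
    and a pure single channel on a vertex (saturation ``vertex_distance``).
    """
    verts = tetra_vertices(vertex_distance)
    # vertex row order is (UV, SW, MW, LW)
    weights = np.array([p.uv, p.sw, p.mw, p.lw])
    pos = weights @ verts
    return float(np.linalg.norm(pos))


def hues(q: ChannelQuad) -> tuple[float, float]:
    """The two hue ratios (hue1, hue2).

    hue1 = UV / mean(LW, MW, SW); hue2 = (LW + UV) / (MW + SW).
    Both equal 1 for spectrally flat (achromatic) quads.
    """
    visible_mean = (q.lw + q.mw + q.sw) / 3.0
    mwsw = q.mw + q.sw
    if visible_mean <= 0:
        raise ValueError("hue1 undefined: LW+MW+SW is zero")
    if mwsw <= 0:
        raise ValueError("hue2 undefined: MW+SW is zero")
    hue1 = q.uv / visible_mean
    hue2 = (q.lw + q.uv) / mwsw
    return float(hue1), float(hue2)


def compute_colour_metrics(
    q: ChannelQuad, vertex_distance: float = TETRA_VERTEX_DISTANCE
) -> ColourMetrics:
    """All four colour metrics for one carapace."""
    h1, h2 = hues(q)
    return ColourMetrics(
        brightness=brightness(q),
        saturation=tetra_saturation(proportions(q), vertex_distance),
        hue1=h1,
        hue2=h2,
    )


def pca_colour_screen(
    prop_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """PCA of cohort channel proportions (covariance matrix).

    Diagnostic used to confirm that fixed hue ratios capture the main axes
    of colour variation; it never redefines the hue formulas.

    Parameters
    ----------
    prop_table
        One row per crab with columns ``lw, mw, sw, uv`` holding channel
        proportions.

    Returns
    -------
    loadings
        4×4 DataFrame, one column per principal component, rows indexed by
        channel.
    variance_explained
        Percent of total variance per component; sums to 100.
    """
    cols = list(CHANNELS)
    x = prop_table[cols].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("PCA screen needs at least 3 individuals")
    cov = np.cov(x, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0:
        raise ValueError("cohort proportions have zero variance")
    pcs = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=cols, columns=pcs)
    variance = pd.Series(100.0 * evals / total, index=pcs, name="variance_explained")
    return loadings, variance


def correlation_screen(
    metrics: pd.DataFrame, threshold: float = 0.7
) -> pd.DataFrame:
    """Flag metric pairs with |Pearson r| at or above ``threshold``.

    Pairs involving a constant column get ``r = NaN`` and are reported as
    undefined rather than flagged.  Returns a long-format DataFrame with
    columns ``metric_a, metric_b, r, flagged``.
    """
    if len(metrics) < 3:
        raise ValueError("correlation screen needs at least 3 rows")
    cols = list(metrics.columns)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        xa = metrics[a].to_numpy(dtype=float)
        xb = metrics[b].to_numpy(dtype=float)
        if np.std(xa) == 0 or np.std(xb) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(xa, xb)[0, 1])
        rows.append(
            {
                "metric_a": a,
                "metric_b": b,
                "r": r,
                "flagged": bool(np.isfinite(r) and abs(r) >= threshold),
            }
        )
    return pd.DataFrame(rows)
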