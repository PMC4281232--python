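"""Synthetic multispectral scenes and cohorts with known ground truth.

Every pipeline stage can be exercised without field data by generating:

* **calibration scenes** — flat grey patches of known reflectance (a 40%
  standard plus an 8-step 2–99% ladder) rendered through a power-law
  camera response and a global illumination factor, with sensor noise;
* **crab images** — an elliptical "carapace" filled with band-limited
  blob texture of controlled dominant scale and contrast over a base
  four-channel colour, embedded in the same photographic setup;
* **cohort tables** — per site × life-stage draws of the six appearance
  metrics from multivariate normals with site- and stage-dependent means
  and inflated juvenile variance, mirroring the structure of the field
  dataset (four sites, three shore zones, juveniles more variable and
  more numerous than adults).

All generators are seed-deterministic and return a *truth record* holding
every generating parameter so tests can compare recovered values against
ground truth.  Rasters are float-valued on the 0–255 raw scale — an
idealised sensor without quantisation, so calibration accuracy is limited
only by noise and fit error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .calibration import GreyStandardLadder, RawMultispectralImage
from .colour import CHANNELS, ChannelQuad, compute_colour_metrics
from .diversity import PHENOTYPE_METRICS

__all__ = [
    "ImageScenario",
    "CohortScenario",
    "make_calibration_scene",
    "make_crab_image",
    "make_cohort",
    "default_cohort_scenario",
    "LADDER_REFLECTANCES",
    "SITES",
    "ZONES",
    "STAGES",
]

#: Nominal reflectances of the 8-step grey-standard ladder (2–99%).
LADDER_REFLECTANCES = np.array([0.02, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 0.99])

SITES = ("Falmouth", "Godrevy", "Helford", "StMawes")
ZONES = ("low", "middle", "upper")
STAGES = ("adult", "juvenile")


@dataclass(frozen=True)
class ImageScenario:
    """Parameters of one synthetic photograph."""

    base_quad: tuple[float, float, float, float] = (90.0, 80.0, 70.0, 40.0)
    pattern_scale_px: float = 16.0
    pattern_contrast: float = 20.0
    noise_sd: float = 0.5
    camera_exponent: float = 2.2
    illumination: float = 1.0
    standard_reflectance: float = 0.40
    image_size: int = 256
    pixels_per_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern_scale_px < 2:
            raise ValueError("pattern length scale must be at least 2 px")
        if self.pattern_contrast < 0:
            raise ValueError("pattern contrast must be non-negative")
        if not 0 < self.standard_reflectance <= 1:
            raise ValueError("standard reflectance must be a fraction in (0, 1]")
        if self.camera_exponent <= 0 or self.illumination <= 0:
            raise ValueError("camera exponent and illumination must be positive")


@dataclass(frozen=True)
class CohortScenario:
    """Parameters of a synthetic field cohort.

    ``cell_means`` maps (site, stage) to a mean vector over the six
    appearance metrics; ``metric_sd`` gives adult-stage SDs per metric and
    juvenile cells have their SDs multiplied by
    ``juvenile_sd_inflation``.  ``cell_n`` gives crabs per cell.
    """

    cell_means: dict[tuple[str, str], dict[str, float]]
    metric_sd: dict[str, float]
    cell_n: dict[tuple[str, str], int]
    juvenile_sd_inflation: float = 1.75
    adult_width_range: tuple[float, float] = (25.0, 60.0)
    juvenile_width_range: tuple[float, float] = (5.0, 24.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for cell, n in self.cell_n.items():
            if n < 2:
                raise ValueError(f"cell {cell}: need n >= 2")
            if cell not in self.cell_means:
                raise ValueError(f"cell {cell}: no mean vector supplied")
        for cell, means in self.cell_means.items():
            if set(means) != set(PHENOTYPE_METRICS):
                raise ValueError(f"cell {cell}: mean vector must cover {PHENOTYPE_METRICS}")
        if set(self.metric_sd) != set(PHENOTYPE_METRICS):
            raise ValueError(f"metric_sd must cover {PHENOTYPE_METRICS}")


def _camera(reflectance: np.ndarray, scenario: ImageScenario, rng: np.random.Generator) -> np.ndarray:
    """Scene reflectance -> raw camera values (power-law response + noise)."""
    radiance = np.clip(scenario.illumination * reflectance, 0.0, 1.0)
    raw = 255.0 * radiance ** (1.0 / scenario.camera_exponent)
    if scenario.noise_sd > 0:
        raw = raw + rng.normal(0.0, scenario.noise_sd, size=raw.shape)
    return np.clip(raw, 0.0, 255.0)


def _patch_layout(n: int) -> dict[str, tuple[slice, slice]]:
    """Pixel regions of the standard and the 8 ladder patches on an n×n canvas."""
    p = n // 10  # patch half-pitch
    layout = {"standard": (slice(p, 3 * p), slice(p, 3 * p))}
    for i in range(len(LADDER_REFLECTANCES)):
        col = p + i * (n - 2 * p) // 8
        layout[f"ladder{i}"] = (slice(n - 2 * p, n - p), slice(col, col + p))
    return layout


def _render(
    reflectance_maps: dict[str, np.ndarray],
    scenario: ImageScenario,
    rng: np.random.Generator,
) -> tuple[RawMultispectralImage, GreyStandardLadder]:
    n = scenario.image_size
    layout = _patch_layout(n)
    rasters = {
        ch: _camera(reflectance_maps[ch], scenario, rng) for ch in CHANNELS
    }
    std_roi = np.zeros((n, n), dtype=bool)
    std_roi[layout["standard"]] = True
    measured = {
        ch: np.array(
            [
                rasters[ch][layout[f"ladder{i}"]].mean()
                for i in range(len(LADDER_REFLECTANCES))
            ]
        )
        for ch in CHANNELS
    }
    raw = RawMultispectralImage(
        rasters=rasters, standard_roi=std_roi, ruler_scale=scenario.pixels_per_mm
    )
    ladder = GreyStandardLadder(
        reflectances=LADDER_REFLECTANCES.copy(), measured=measured
    )
    return raw, ladder


def _base_reflectance_maps(scenario: ImageScenario) -> dict[str, np.ndarray]:
    """Grey background with the standard and ladder patches stamped in."""
    n = scenario.image_size
    layout = _patch_layout(n)
    maps = {ch: np.full((n, n), 0.15) for ch in CHANNELS}
    for ch in CHANNELS:
        maps[ch][layout["standard"]] = scenario.standard_reflectance
        for i, r in enumerate(LADDER_REFLECTANCES):
            maps[ch][layout[f"ladder{i}"]] = r
    return maps


def make_calibration_scene(
    scenario: ImageScenario,
) -> tuple[RawMultispectralImage, GreyStandardLadder, dict[str, Any]]:
    """Render a patches-only scene for calibration round-trip tests.

    Besides the standard and the embedded ladder, four extra "probe"
    patches of known reflectance are stamped in so recovery accuracy can
    be checked away from the fitted ladder points.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.image_size
    maps = _base_reflectance_maps(scenario)
    probe_reflectances = [0.08, 0.25, 0.50, 0.70]
    probes: dict[str, tuple[slice, slice]] = {}
    p = n // 10
    for i, r in enumerate(probe_reflectances):
        rows = slice(4 * p, 6 * p)
        cols = slice(p + i * 2 * p, p + i * 2 * p + p)
        probes[f"probe{i}"] = (rows, cols)
        for ch in CHANNELS:
            maps[ch][rows, cols] = r
    raw, ladder = _render(maps, scenario, rng)
    truth = {
        "scenario": scenario,
        "standard_region": _patch_layout(n)["standard"],
        "probe_regions": probes,
        "probe_reflectances": dict(zip(probes, probe_reflectances)),
        "standard_reflectance": scenario.standard_reflectance,
    }
    return raw, ladder, truth


def band_limited_noise(
    shape: tuple[int, int], scale_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance noise whose power concentrates at spatial period ``scale_px``.

    White noise is annulus-filtered in the Fourier domain to periods
    within half an octave of the target scale, producing mottled
    blob-like texture with a controllable dominant granularity band.
    """
    noise = rng.standard_normal(shape)
    spec = np.fft.fft2(noise)
    fy = np.fft.fftfreq(shape[0])
    fx = np.fft.fftfreq(shape[1])
    f = np.hypot(fy[:, None], fx[None, :])
    with np.errstate(divide="ignore"):
        period = np.where(f > 0, 1.0 / np.maximum(f, 1e-300), np.inf)
    lo, hi = scale_px / 2**0.25, scale_px * 2**0.25
    mask = (period >= lo) & (period < hi)
    if not mask.any():
        raise ValueError(f"scale {scale_px} px unresolvable at image size {shape}")
    spec *= mask
    tex = np.real(np.fft.ifft2(spec))
    return (tex - tex.mean()) / tex.std()


def make_crab_image(
    scenario: ImageScenario,
) -> tuple[RawMultispectralImage, np.ndarray, dict[str, Any]]:
    """Render a patterned elliptical carapace in the photographic setup.

    The carapace ellipse is filled, in every channel, with the base-quad
    reflectance plus a shared band-limited texture of the scenario's
    length scale and contrast (contrast in 0–255 calibrated units).  The
    truth record carries the expected colour metrics of the base quad and
    the expected dominant marking size.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.image_size
    maps = _base_reflectance_maps(scenario)
    yy, xx = np.mgrid[:n, :n]
    cy, cx = n * 0.45, n * 0.55
    ry, rx = n * 0.22, n * 0.28
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    unresolvable = scenario.pattern_scale_px > min(ry, rx)
    if unresolvable:
        import warnings

        warnings.warn(
            "pattern length scale exceeds carapace radius; dominant marking "
            "size will not be resolvable",
            stacklevel=2,
        )
    if scenario.pattern_contrast > 0:
        texture = band_limited_noise((n, n), scenario.pattern_scale_px, rng)
    else:
        texture = np.zeros((n, n))
    quad = ChannelQuad(*scenario.base_quad)
    for ch, base in zip(CHANNELS, scenario.base_quad):
        refl = (base + scenario.pattern_contrast * texture) / 255.0
        maps[ch][mask] = np.clip(refl, 0.005, 1.0)[mask]
    raw, ladder = _render(maps, scenario, rng)
    expected = compute_colour_metrics(quad)
    truth = {
        "scenario": scenario,
        "ladder": ladder,
        "expected_colour": expected,
        "expected_marking_size_px": scenario.pattern_scale_px,
        "pattern_unresolvable": bool(unresolvable or scenario.pattern_contrast == 0),
        "roi_pixels": int(mask.sum()),
    }
    return raw, mask, truth


def default_cohort_scenario(seed: int = 0) -> CohortScenario:
    """Cohort scenario mirroring the field study's structure.

    Cell sample sizes follow the field cohort (677 crabs over four sites,
    juveniles outnumbering adults); cell means encode the qualitative
    effect structure the study reports — juveniles brighter, more
    saturated, with higher proportion energy and smaller markings;
    Helford crabs darker, bluer-green (lower hue) and more saturated;
    St Mawes patterns of highest contrast — and juvenile cells have
    1.75× the adult metric SDs, making juveniles the more variable stage.
    """
    cell_n = {
        ("Falmouth", "juvenile"): 193,
        ("Falmouth", "adult"): 71,
        ("Godrevy", "juvenile"): 63,
        ("Godrevy", "adult"): 29,
        ("Helford", "juvenile"): 116,
        ("Helford", "adult"): 42,
        ("StMawes", "juvenile"): 136,
        ("StMawes", "adult"): 27,
    }
    adult_means = {
        "Falmouth": dict(
            brightness=75, saturation=0.060, hue=1.05, marking_size=30,
            total_energy=90, proportion_energy=0.18,
        ),
        "Godrevy": dict(
            brightness=68, saturation=0.050, hue=1.00, marking_size=28,
            total_energy=45, proportion_energy=0.15,
        ),
        "Helford": dict(
            brightness=58, saturation=0.100, hue=0.85, marking_size=30,
            total_energy=40, proportion_energy=0.15,
        ),
        "StMawes": dict(
            brightness=72, saturation=0.080, hue=1.02, marking_size=29,
            total_energy=150, proportion_energy=0.19,
        ),
    }
    juvenile_shift = dict(
        brightness=+20, saturation=+0.030, hue=-0.05, marking_size=-18,
        total_energy=+10, proportion_energy=+0.12,
    )
    cell_means: dict[tuple[str, str], dict[str, float]] = {}
    for site in SITES:
        cell_means[(site, "adult")] = dict(adult_means[site])
        cell_means[(site, "juvenile")] = {
            m: adult_means[site][m] + juvenile_shift[m] for m in PHENOTYPE_METRICS
        }
    metric_sd = dict(
        brightness=10.0, saturation=0.018, hue=0.07, marking_size=6.0,
        total_energy=30.0, proportion_energy=0.05,
    )
    return CohortScenario(
        cell_means=cell_means, metric_sd=metric_sd, cell_n=cell_n, seed=seed
    )


#: Physical lower bounds the metric draws are clipped to.
_METRIC_FLOOR = dict(
    brightness=1.0, saturation=0.0, hue=0.01, marking_size=2.0,
    total_energy=0.1, proportion_energy=0.01,
)


def make_cohort(scenario: CohortScenario) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Draw a cohort table from a scenario.

    Metrics are multivariate-normal (diagonal covariance) per cell,
    clipped to physical ranges; carapace widths are uniform within the
    stage's range so the 25 mm rule separates stages exactly; zone and
    sex are assigned uniformly at random.  Returns the table and a truth
    record with every cell mean and SD actually used.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = []
    crab_id = 0
    truth_cells = {}
    for (site, stage), n in sorted(scenario.cell_n.items()):
        means = scenario.cell_means[(site, stage)]
        infl = scenario.juvenile_sd_inflation if stage == "juvenile" else 1.0
        sds = {m: scenario.metric_sd[m] * infl for m in PHENOTYPE_METRICS}
        truth_cells[(site, stage)] = {"mean": dict(means), "sd": dict(sds), "n": n}
        draws = {
            m: np.clip(
                rng.normal(means[m], sds[m], size=n),
                _METRIC_FLOOR[m],
                1.0 if m == "proportion_energy" else np.inf,
            )
            for m in PHENOTYPE_METRICS
        }
        lo, hi = (
            scenario.juvenile_width_range
            if stage == "juvenile"
            else scenario.adult_width_range
        )
        widths = rng.uniform(lo, hi, size=n)
        zones = rng.choice(ZONES, size=n)
        sexes = rng.choice(["f", "m"], size=n)
        for i in range(n):
            rows.append(
                {
                    "id": f"crab{crab_id:04d}",
                    "site": site,
                    "zone": zones[i],
                    "sex": sexes[i],
                    "stage": stage,
                    "carapace_width_mm": widths[i],
                    **{m: draws[m][i] for m in PHENOTYPE_METRICS},
                }
            )
            crab_id += 1
    cohort = pd.DataFrame(rows)
    truth = {"cells": truth_cells, "scenario": scenario}
    return cohort, truth
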