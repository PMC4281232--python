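"""Multispectral image calibration: linearization, equalization, scaling.

Raw camera values respond nonlinearly to light.  Calibration proceeds in
three steps, each anchored to an in-frame Spectralon grey standard:

1. **Linearization** — fit the camera response per channel from a ladder of
   grey standards of known reflectance (nominally eight, 2–99%) and invert
   it so image values become proportional to scene radiance.
2. **Equalization and reflectance scaling** — rescale each channel so the
   in-frame grey standard (40% reflectance by default) reads its true
   value on a scale where 255 equals 100% reflectance.  This removes
   differences in ambient illumination between photographs.
3. **Spatial standardization** — resize every image to a common
   pixels-per-mm scale (from the in-frame ruler) so pattern marking sizes
   are comparable across crabs.

The carapace region of interest (ROI) then yields the mean reflectance
per channel (a :class:`~carapace_pheno.colour.ChannelQuad`) and a
mean-filled brightness raster ready for granularity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
from scipy.interpolate import PchipInterpolator
from skimage.transform import rescale as _sk_rescale

from .colour import CHANNELS, ChannelQuad

__all__ = [
    "GreyStandardLadder",
    "ResponseCurve",
    "RawMultispectralImage",
    "CalibratedImage",
    "fit_linearization",
    "linearize",
    "equalize_and_scale",
    "rescale_to_common_scale",
    "extract_roi",
    "DEFAULT_PIXELS_PER_MM",
]

#: Canonical spatial scale images are resized to (pixels per mm).
DEFAULT_PIXELS_PER_MM = 10.0

#: Raw value treated as sensor saturation (8-bit clip point).
SATURATION_VALUE = 255.0


@dataclass(frozen=True)
class GreyStandardLadder:
    """Grey-standard ladder: known reflectances and measured raw values.

    ``measured`` maps each channel name to the mean raw pixel value
    (0–255) of each ladder step in that channel.
    """

    reflectances: np.ndarray
    measured: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        refl = np.asarray(self.reflectances, dtype=float)
        object.__setattr__(self, "reflectances", refl)
        if refl.ndim != 1 or len(refl) < 3:
            raise ValueError("ladder needs at least 3 reflectance steps")
        if np.any(refl <= 0) or np.any(refl > 1):
            raise ValueError("reflectances must be fractions in (0, 1]")
        if np.any(np.diff(refl) <= 0):
            raise ValueError("reflectances must be strictly increasing")
        meas = {ch: np.asarray(v, dtype=float) for ch, v in self.measured.items()}
        object.__setattr__(self, "measured", meas)
        for ch, vals in meas.items():
            if len(vals) != len(refl):
                raise ValueError(f"channel {ch!r}: length mismatch with reflectances")
            if np.any(vals < 0):
                raise ValueError(f"channel {ch!r}: negative measured values")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.measured)


@dataclass(frozen=True)
class ResponseCurve:
    """Per-channel monotone mapping raw value -> linear (reflectance) value.

    The linear output is on the 0–255 scale (255 = 100% reflectance as
    predicted by the ladder fit); 0 maps to 0.  ``r_squared`` reports, per
    channel, the R² of linearized ladder values against the true ladder
    reflectances.
    """

    maps: dict[str, Callable[[np.ndarray], np.ndarray]]
    r_squared: dict[str, float]
    model: str = "power"
    params: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __call__(self, channel: str, values: np.ndarray) -> np.ndarray:
        return self.maps[channel](np.asarray(values, dtype=float))


@dataclass
class RawMultispectralImage:
    """Four co-registered rasters (LW/MW/SW/UV) straight off the camera.

    ``standard_roi`` is a boolean mask of the in-frame grey standard;
    ``ruler_scale`` is pixels per mm from the in-frame ruler.  ``linearized``
    marks images already mapped through a response curve.
    """

    rasters: dict[str, np.ndarray]
    standard_roi: np.ndarray
    ruler_scale: float
    linearized: bool = False
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {r.shape for r in self.rasters.values()}
        if len(shapes) != 1:
            raise ValueError("all channel rasters must share one shape")
        (shape,) = shapes
        if self.standard_roi.shape != shape:
            raise ValueError("standard_roi must match raster dimensions")
        if not self.standard_roi.any():
            raise ValueError("standard_roi is empty")
        if self.ruler_scale is not None and self.ruler_scale <= 0:
            raise ValueError("ruler_scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.rasters.values())).shape


@dataclass
class CalibratedImage:
    """Reflectance-scaled image: value 255 means 100% reflectance."""

    rasters: dict[str, np.ndarray]
    mm_per_pixel: float
    roi_mask: np.ndarray | None = None
    standard_roi: np.ndarray | None = None
    saturated: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.rasters.values())).shape

    def brightness_raster(self) -> np.ndarray:
        return np.mean([self.rasters[ch] for ch in CHANNELS], axis=0)


def _check_monotone(
    refl: np.ndarray, vals: np.ndarray, channel: str, tol: float
) -> None:
    if np.any(np.diff(vals) < -tol):
        raise ValueError(
            f"channel {channel!r}: measured ladder values decrease with "
            "reflectance; ladder is non-monotone (bad photograph?)"
        )


def fit_linearization(
    ladder: GreyStandardLadder,
    model: Literal["power", "spline"] = "power",
    monotone_tol: float = 1.0,
) -> ResponseCurve:
    """Fit the camera response from a grey-standard ladder and invert it.

    The default model is a monotone power law ``value = a·reflectance^b``
    fitted per channel by least squares in log–log space; its inverse
    ``linear(v) = 255·(v/a)^(1/b)`` maps raw values to the linear
    reflectance scale.  A monotone PCHIP spline mode is available for
    ladders a power law cannot describe.

    Ladder steps at the sensor clip point (raw ≥ 254.5, i.e. a saturated
    photograph of that standard) carry no response information and are
    excluded from the fit.  Decreases larger than ``monotone_tol`` raw
    units between adjacent steps reject the ladder as non-monotone;
    smaller wobble is treated as measurement noise.
    """
    refl_all = ladder.reflectances
    maps: dict[str, Callable[[np.ndarray], np.ndarray]] = {}
    r2: dict[str, float] = {}
    params: dict[str, tuple[float, ...]] = {}
    for ch, vals_all in ladder.measured.items():
        usable = vals_all < SATURATION_VALUE - 0.5
        refl, vals = refl_all[usable], vals_all[usable]
        if len(vals) < 3:
            raise ValueError(
                f"channel {ch!r}: fewer than 3 unsaturated ladder points"
            )
        _check_monotone(refl, vals, ch, monotone_tol)
        if model == "power":
            pos = vals > 0
            if pos.sum() < 3:
                raise ValueError(f"channel {ch!r}: fewer than 3 usable ladder points")
            b, loga = np.polyfit(np.log(refl[pos]), np.log(vals[pos]), 1)
            a = float(np.exp(loga))
            if b <= 0:
                raise ValueError(f"channel {ch!r}: non-increasing fitted response")

            def mapping(v: np.ndarray, a: float = a, b: float = b) -> np.ndarray:
                v = np.asarray(v, dtype=float)
                return 255.0 * np.power(np.clip(v, 0.0, None) / a, 1.0 / b)

            params[ch] = (a, float(b))
        elif model == "spline":
            # collapse tied measured values so PCHIP gets strictly increasing x
            xs, idx = np.unique(vals, return_index=True)
            ys = np.array([refl[vals == x].mean() for x in xs])
            if xs[0] > 0:
                xs = np.concatenate([[0.0], xs])
                ys = np.concatenate([[0.0], ys])
            interp = PchipInterpolator(xs, ys, extrapolate=True)

            def mapping(v: np.ndarray, f: PchipInterpolator = interp) -> np.ndarray:
                v = np.asarray(v, dtype=float)
                return 255.0 * np.clip(f(v), 0.0, None)

            params[ch] = tuple(xs)
        else:
            raise ValueError(f"unknown linearization model {model!r}")
        maps[ch] = mapping
        # diagnostic: linearized ladder vs true reflectance
        pred = mapping(vals) / 255.0
        ss_res = float(np.sum((pred - refl) ** 2))
        ss_tot = float(np.sum((refl - refl.mean()) ** 2))
        r2[ch] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ResponseCurve(maps=maps, r_squared=r2, model=model, params=params)


def linearize(raw: RawMultispectralImage, curve: ResponseCurve) -> RawMultispectralImage:
    """Map every pixel through its channel's inverse response.

    Also flags raw pixels at the 8-bit clip point (255) as saturated so
    downstream ROI means can exclude them, the numeric analogue of
    avoiding specular highlights when drawing ROIs.
    """
    missing = set(raw.rasters) - set(curve.maps)
    if missing:
        raise ValueError(f"response curve missing channels: {sorted(missing)}")
    saturated = np.zeros(raw.shape, dtype=bool)
    out: dict[str, np.ndarray] = {}
    for ch, arr in raw.rasters.items():
        arr = np.asarray(arr, dtype=float)
        if np.any(arr < 0) or np.any(arr > 255):
            raise ValueError(f"channel {ch!r}: raw values outside [0, 255]")
        saturated |= arr >= SATURATION_VALUE
        out[ch] = curve(ch, arr)
    return RawMultispectralImage(
        rasters=out,
        standard_roi=raw.standard_roi,
        ruler_scale=raw.ruler_scale,
        linearized=True,
        saturated=saturated,
    )


def equalize_and_scale(
    linear: RawMultispectralImage | CalibratedImage,
    standard_reflectance: float = 0.40,
) -> CalibratedImage:
    """Equalize to the grey standard and scale channels to reflectance.

    Per channel, pixels are multiplied by a single factor chosen so the
    mean over the standard region equals ``standard_reflectance × 255``
    (102 for the default 40% standard).  Idempotent: equalizing an already
    calibrated image leaves it unchanged.
    """
    if not 0 < standard_reflectance <= 1:
        raise ValueError("standard_reflectance must be a fraction in (0, 1]")
    if isinstance(linear, RawMultispectralImage):
        std_roi = linear.standard_roi
        mm_per_pixel = 1.0 / linear.ruler_scale
    else:
        if linear.standard_roi is None:
            raise ValueError("image carries no standard_roi to equalize against")
        std_roi = linear.standard_roi
        mm_per_pixel = linear.mm_per_pixel
    target = standard_reflectance * 255.0
    out: dict[str, np.ndarray] = {}
    for ch, arr in linear.rasters.items():
        std_mean = float(np.asarray(arr, dtype=float)[std_roi].mean())
        if std_mean <= 1e-9:
            raise ValueError(
                f"channel {ch!r}: grey standard reads zero; failed photograph"
            )
        out[ch] = np.asarray(arr, dtype=float) * (target / std_mean)
    return CalibratedImage(
        rasters=out,
        mm_per_pixel=mm_per_pixel,
        roi_mask=getattr(linear, "roi_mask", None),
        standard_roi=std_roi,
        saturated=linear.saturated,
    )


def rescale_to_common_scale(
    img: CalibratedImage, target_mm_per_pixel: float = 1.0 / DEFAULT_PIXELS_PER_MM
) -> CalibratedImage:
    """Resize to the canonical mm-per-pixel so marking sizes are comparable."""
    if img.mm_per_pixel is None or img.mm_per_pixel <= 0:
        raise ValueError("image has no valid spatial scale (missing ruler?)")
    if target_mm_per_pixel <= 0:
        raise ValueError("target scale must be positive")
    factor = img.mm_per_pixel / target_mm_per_pixel
    if abs(factor - 1.0) < 1e-12:
        return replace(img)

    def _resize(arr: np.ndarray, order: int) -> np.ndarray:
        return _sk_rescale(
            arr.astype(float),
            factor,
            order=order,
            anti_aliasing=factor < 1,
            preserve_range=True,
        )

    rasters = {ch: _resize(a, order=1) for ch, a in img.rasters.items()}
    roi = None if img.roi_mask is None else _resize(img.roi_mask.astype(float), 0) > 0.5
    std = (
        None
        if img.standard_roi is None
        else _resize(img.standard_roi.astype(float), 0) > 0.5
    )
    sat = (
        None
        if img.saturated is None
        else _resize(img.saturated.astype(float), 0) > 0.5
    )
    return CalibratedImage(
        rasters=rasters,
        mm_per_pixel=target_mm_per_pixel,
        roi_mask=roi,
        standard_roi=std,
        saturated=sat,
    )


def extract_roi(img: CalibratedImage) -> tuple[ChannelQuad, np.ndarray]:
    """Measure the carapace ROI.

    Returns the per-channel mean reflectance over the ROI mask (excluding
    pixels flagged as saturated) and the brightness raster prepared for
    granularity analysis: pixels outside the mask are filled with the
    masked mean so the mask boundary injects minimal spurious
    low-frequency energy.
    """
    if img.roi_mask is None or not img.roi_mask.any():
        raise ValueError("ROI mask is empty")
    valid = img.roi_mask.copy()
    if img.saturated is not None:
        valid &= ~img.saturated
        if not valid.any():
            raise ValueError("ROI entirely saturated")
        n_dropped = int(img.roi_mask.sum() - valid.sum())
        if n_dropped:
            warnings.warn(
                f"{n_dropped} saturated pixels excluded from ROI means",
                stacklevel=2,
            )
    means = {ch: float(img.rasters[ch][valid].mean()) for ch in CHANNELS}
    quad = ChannelQuad(**means)
    bright = img.brightness_raster()
    pattern = np.full_like(bright, float(bright[valid].mean()))
    pattern[valid] = bright[valid]
    return quad, pattern
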