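"""Hue/saturation/intensity color model and positive-pixel classification.

Chromogenic stains (aniline blue, Biebrich scarlet, PAS magenta, DAB brown)
occupy narrow arcs of the color circle.  A pixel is called *positive* for a
stain when its hue lies within a circular tolerance (``hue_width``) of the
stain's hue center, its saturation is high enough to distinguish dye from
gray tissue, and its intensity falls in the countable range.  Positive
pixels are binned weak/medium/strong by intensity (strong = darkest), the
convention of slide-scanner positive-pixel-count tools.

Hue is a fraction of the color circle in [0, 1) with red at 0, computed with
the polar (Gonzalez–Woods) HSI formula; saturation is ``1 - 3*min/(R+G+B)``;
intensity is the plain channel mean on [0, 255].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PixelClass",
    "StainProfile",
    "PixelCountResult",
    "rgb_to_hsi",
    "circular_hue_distance",
    "classify_pixels",
    "percent_positive",
    "calibrate_hue",
    "CalibrationError",
]


class CalibrationError(ValueError):
    """No qualifying pixels were available for hue calibration."""


class PixelClass(enum.IntEnum):
    """Codes used in classification label rasters."""

    OUTSIDE = 0     # not examined (outside the region mask)
    BACKGROUND = 1  # glass / lumen: intensity above tissue_intensity_max
    NEGATIVE = 2    # tissue failing the hue/saturation test
    WEAK = 3
    MEDIUM = 4
    STRONG = 5


@dataclass(frozen=True)
class StainProfile:
    """Circular-hue classification parameters for one chromogen or dye.

    Parameters
    ----------
    name : str
        Stain identifier (e.g. ``"trichrome_blue"``).
    hue_center : float
        Center of the acceptance arc, fraction of the color circle in [0, 1).
    hue_width : float
        Circular-distance tolerance in (0, 1]; a pixel passes when its hue is
        within ``hue_width`` of ``hue_center`` (inclusive).  Note the maximum
        circular distance is 0.5, so a width of 0.5 accepts every hue.
    saturation_min : float
        Minimum saturation for a positive call; default 0.04.
    intensity_strong_upper, intensity_medium_upper, intensity_weak_upper : float
        Intensity bin edges: strong < s_up <= medium < m_up <= weak <= w_up.
        Hue-passing pixels brighter than ``intensity_weak_upper`` are too
        faint to count and are called negative.
    tissue_intensity_max : float
        Pixels brighter than this are glass background, not tissue.
    """

    name: str
    hue_center: float
    hue_width: float
    saturation_min: float = 0.04
    intensity_strong_upper: float = 100.0
    intensity_medium_upper: float = 175.0
    intensity_weak_upper: float = 220.0
    tissue_intensity_max: float = 240.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue_center < 1.0:
            raise ValueError(f"hue_center must be in [0, 1): {self.hue_center}")
        if not 0.0 < self.hue_width <= 1.0:
            raise ValueError(f"hue_width must be in (0, 1]: {self.hue_width}")
        if not 0.0 <= self.saturation_min <= 1.0:
            raise ValueError(f"saturation_min must be in [0, 1]: {self.saturation_min}")
        if not (
            self.intensity_strong_upper
            < self.intensity_medium_upper
            < self.intensity_weak_upper
            <= self.tissue_intensity_max
        ):
            raise ValueError(
                "intensity thresholds must satisfy strong < medium < weak <= tissue_max"
            )

    @classmethod
    def from_dict(cls, name: str, params: dict) -> "StainProfile":
        """Build a profile from a config mapping.

        ``hue_center_degrees`` / ``hue_width_degrees`` are accepted and
        converted to circle fractions.
        """
        p = dict(params)
        if "hue_center_degrees" in p:
            p["hue_center"] = (p.pop("hue_center_degrees") / 360.0) % 1.0
        if "hue_width_degrees" in p:
            p["hue_width"] = p.pop("hue_width_degrees") / 360.0
        return cls(name=name, **p)

    def to_dict(self) -> dict:
        d = {
            "hue_center": self.hue_center,
            "hue_width": self.hue_width,
            "saturation_min": self.saturation_min,
            "intensity_strong_upper": self.intensity_strong_upper,
            "intensity_medium_upper": self.intensity_medium_upper,
            "intensity_weak_upper": self.intensity_weak_upper,
            "tissue_intensity_max": self.tissue_intensity_max,
        }
        return d

    def with_(self, **kwargs) -> "StainProfile":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PixelCountResult:
    """Positive/negative/background pixel counts for one stain in one region."""

    n_weak: int
    n_medium: int
    n_strong: int
    n_negative: int
    n_background: int
    region_label: str = ""

    def __post_init__(self) -> None:
        for f in ("n_weak", "n_medium", "n_strong", "n_negative", "n_background"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def n_positive(self) -> int:
        return self.n_weak + self.n_medium + self.n_strong

    @property
    def n_tissue(self) -> int:
        """Tissue pixels examined (positive + negative; background excluded)."""
        return self.n_positive + self.n_negative

    @property
    def n_total(self) -> int:
        return self.n_tissue + self.n_background


def _as_rgb_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    return image.astype(np.float64)


def rgb_to_hsi(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an 8-bit RGB raster to hue, saturation, intensity planes.

    Returns
    -------
    hue : ndarray of float
        Circle fraction in [0, 1), red at 0; NaN where the pixel is
        achromatic (R = G = B, saturation 0).
    saturation : ndarray of float
        ``1 - 3*min(R,G,B)/(R+G+B)`` in [0, 1]; 0 for achromatic pixels.
    intensity : ndarray of float
        ``(R + G + B) / 3`` on the [0, 255] scale.
    """
    rgb = _as_rgb_float(image)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    intensity = total / 3.0

    minc = np.minimum(np.minimum(r, g), b)
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * minc / total, 0.0)

    num = 0.5 * ((r - g) + (r - b))
    den2 = (r - g) ** 2 + (r - b) * (g - b)
    achromatic = den2 <= 0  # zero iff R = G = B
    den = np.sqrt(np.where(achromatic, 1.0, den2))
    cosang = np.clip(num / den, -1.0, 1.0)
    theta = np.arccos(cosang) / (2.0 * np.pi)
    hue = np.where(b > g, 1.0 - theta, theta)
    hue = np.where(achromatic, np.nan, hue)
    saturation = np.where(achromatic, 0.0, saturation)
    return hue, saturation, intensity


def circular_hue_distance(h1, h2):
    """Shortest distance between two hues on the unit color circle.

    Both arguments must be fractions in [0, 1).  The result is in [0, 0.5]
    and symmetric; 0 iff the hues are equal modulo 1.  Accepts scalars or
    broadcastable arrays.
    """
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    for h in (h1, h2):
        valid = np.isnan(h) | ((h >= 0.0) & (h < 1.0))
        if not np.all(valid):
            raise ValueError("hues must be in [0, 1)")
    d = np.abs(h1 - h2)
    out = np.minimum(d, 1.0 - d)
    return float(out) if out.ndim == 0 else out


def classify_pixels(
    image: np.ndarray,
    profile: StainProfile,
    region_mask: np.ndarray | None = None,
    region_label: str = "",
) -> tuple[PixelCountResult, np.ndarray]:
    """Classify every masked pixel as background / negative / weak / medium / strong.

    Within the mask, a pixel is background when its intensity exceeds
    ``profile.tissue_intensity_max``; otherwise positive when its hue lies
    within ``profile.hue_width`` of ``profile.hue_center`` (circularly,
    boundary inclusive), its saturation is at least ``profile.saturation_min``
    and its intensity does not exceed ``profile.intensity_weak_upper``;
    otherwise negative.  Positive pixels are binned by intensity with strong
    the darkest bin.

    Returns the count result and a label raster of :class:`PixelClass` codes
    (``OUTSIDE`` for unmasked pixels), suitable for rendering markup images.
    """
    rgb = _as_rgb_float(image)
    shape = rgb.shape[:2]
    if region_mask is None:
        region_mask = np.ones(shape, dtype=bool)
    else:
        region_mask = np.asarray(region_mask).astype(bool)
        if region_mask.shape != shape:
            raise ValueError(
                f"mask shape {region_mask.shape} does not match image shape {shape}"
            )

    hue, sat, inten = rgb_to_hsi(rgb)

    labels = np.zeros(shape, dtype=np.uint8)  # OUTSIDE
    background = region_mask & (inten > profile.tissue_intensity_max)
    tissue = region_mask & ~background

    with np.errstate(invalid="ignore"):
        d = np.abs(hue - profile.hue_center)
        hue_ok = np.minimum(d, 1.0 - d) <= profile.hue_width
    hue_ok &= ~np.isnan(hue)
    positive = (
        tissue
        & hue_ok
        & (sat >= profile.saturation_min)
        & (inten <= profile.intensity_weak_upper)
    )

    strong = positive & (inten < profile.intensity_strong_upper)
    medium = positive & ~strong & (inten < profile.intensity_medium_upper)
    weak = positive & ~strong & ~medium
    negative = tissue & ~positive

    labels[background] = PixelClass.BACKGROUND
    labels[negative] = PixelClass.NEGATIVE
    labels[weak] = PixelClass.WEAK
    labels[medium] = PixelClass.MEDIUM
    labels[strong] = PixelClass.STRONG

    result = PixelCountResult(
        n_weak=int(weak.sum()),
        n_medium=int(medium.sum()),
        n_strong=int(strong.sum()),
        n_negative=int(negative.sum()),
        n_background=int(background.sum()),
        region_label=region_label,
    )
    return result, labels


def percent_positive(result: PixelCountResult) -> float:
    """Percent of tissue pixels that are stain-positive.

    Background (glass) pixels are excluded from the denominator.  Returns NaN
    when the region contains no tissue pixels: an empty region is undefined,
    not 0% positive.
    """
    if result.n_tissue == 0:
        return float("nan")
    return 100.0 * result.n_positive / result.n_tissue


def calibrate_hue(
    image: np.ndarray,
    sample_mask: np.ndarray,
    saturation_min: float = 0.04,
) -> float:
    """Circular mean hue of the dye pixels under ``sample_mask``.

    Used to measure a stain's hue per slide and average the per-slide values
    into a panel-wide profile center.  Only pixels with saturation at least
    ``saturation_min`` contribute.  The mean is circular (angles averaged as
    unit vectors), so samples straddling the red wrap-around average
    correctly — e.g. hues {0.98, 0.02} calibrate to 0.0, not 0.5.

    Raises
    ------
    CalibrationError
        If no masked pixel is sufficiently saturated.
    """
    hue, sat, _ = rgb_to_hsi(image)
    sample_mask = np.asarray(sample_mask).astype(bool)
    if sample_mask.shape != hue.shape:
        raise ValueError("sample_mask shape does not match image")
    sel = sample_mask & ~np.isnan(hue) & (sat >= saturation_min)
    if not sel.any():
        raise CalibrationError(
            "no masked pixels meet the saturation threshold for hue calibration"
        )
    ang = hue[sel] * 2.0 * np.pi
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2.0 * np.pi)
    return float(mean % 1.0)
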