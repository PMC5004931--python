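"""Independent scalar reference implementations used as test oracles.

Pure-Python, per-pixel arithmetic with no numpy vectorization, kept
deliberately separate from the package's vectorized code paths.
"""

from __future__ import annotations

import math

# label codes mirrored from the package's PixelClass (asserted in tests)
OUTSIDE, BACKGROUND, NEGATIVE, WEAK, MEDIUM, STRONG = range(6)


def scalar_hsi(r: float, g: float, b: float) -> tuple[float | None, float, float]:
    """Polar HSI of one RGB triplet; hue None when achromatic."""
    total = r + g + b
    intensity = total / 3.0
    if r == g == b:
        return None, 0.0, intensity
    saturation = 1.0 - 3.0 * min(r, g, b) / total
    num = 0.5 * ((r - g) + (r - b))
    den = math.sqrt((r - g) ** 2 + (r - b) * (g - b))
    theta = math.acos(max(-1.0, min(1.0, num / den))) / (2.0 * math.pi)
    hue = 1.0 - theta if b > g else theta
    return hue, saturation, intensity


def scalar_circular_distance(h1: float, h2: float) -> float:
    d = abs(h1 - h2)
    return min(d, 1.0 - d)


def scalar_classify_pixel(rgb, profile) -> int:
    """Classify one pixel with a StainProfile, per-scalar arithmetic."""
    r, g, b = (float(v) for v in rgb)
    hue, sat, inten = scalar_hsi(r, g, b)
    if inten > profile.tissue_intensity_max:
        return BACKGROUND
    positive = (
        hue is not None
        and scalar_circular_distance(hue, profile.hue_center) <= profile.hue_width
        and sat >= profile.saturation_min
        and inten <= profile.intensity_weak_upper
    )
    if not positive:
        return NEGATIVE
    if inten < profile.intensity_strong_upper:
        return STRONG
    if inten < profile.intensity_medium_upper:
        return MEDIUM
    return WEAK


def scalar_count_classes(image, mask, profile) -> dict[str, int]:
    """Count the five classes over a masked raster, one pixel at a time."""
    counts = {"weak": 0, "medium": 0, "strong": 0, "negative": 0, "background": 0}
    names = {WEAK: "weak", MEDIUM: "medium", STRONG: "strong",
             NEGATIVE: "negative", BACKGROUND: "background"}
    h, w = image.shape[:2]
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            counts[names[scalar_classify_pixel(image[i, j], profile)]] += 1
    return counts
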