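"""Image and table I/O plus provenance sidecars.

Images are plain 8-bit RGB TIFF or PNG region exports (pyramidal whole-slide
containers are out of scope).  Every output file written by the pipeline can
carry a JSON provenance sidecar (config hash, seed, package version) so
deterministic stages reproduce bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .color import PixelClass

__all__ = [
    "read_image",
    "write_image",
    "write_label_png",
    "markup_image",
    "write_provenance",
]

#: Display colors for classification markup images, one per pixel class.
MARKUP_COLORS = {
    PixelClass.OUTSIDE: (0, 0, 0),
    PixelClass.BACKGROUND: (255, 255, 255),
    PixelClass.NEGATIVE: (64, 112, 255),
    PixelClass.WEAK: (255, 255, 0),
    PixelClass.MEDIUM: (255, 128, 0),
    PixelClass.STRONG: (200, 0, 0),
}


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG or TIFF); alpha channels are dropped."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[-1] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"{path} is not an RGB image (shape {img.shape})")
    if img.dtype != np.uint8:
        raise ValueError(f"{path} must be 8-bit, got dtype {img.dtype}")
    return img


def write_image(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image)


def write_label_png(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label raster as a single-channel PNG."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.asarray(labels, dtype=np.uint8))


def markup_image(class_raster: np.ndarray) -> np.ndarray:
    """Render a five-class markup PNG raster from a classification result."""
    out = np.zeros((*class_raster.shape, 3), dtype=np.uint8)
    for cls, rgb in MARKUP_COLORS.items():
        out[class_raster == int(cls)] = rgb
    return out


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Write a ``<output>.provenance.json`` sidecar next to an output file."""
    from . import __version__

    sidecar = Path(str(path) + ".provenance.json")
    doc = {
        "output": Path(path).name,
        "config_hash": config_hash(config),
        "config": config,
        "seed": seed,
        "renomorph_version": __version__,
    }
    sidecar.write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")
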