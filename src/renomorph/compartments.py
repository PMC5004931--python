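"""Anatomic compartments of the renal biopsy and stripe-width geometry.

The metrics in this package are stratified by compartment: cortex, the outer
and inner stripes of the outer medulla, any remaining medulla, plus excluded
regions (typically glomeruli, which are omitted from microvessel analysis).
Compartment delineation is manual in the underlying workflow, so this module
ingests annotations — integer label-mask PNGs or named polygons — rather
than inferring anatomy from the image.

The stripe-width "digital ruler" measures the distance between two annotated
boundary polylines (e.g. the cortico-medullary junction and the outer/inner
stripe interface) as the median of perpendicular distances sampled at
regular arc-length intervals.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

__all__ = [
    "Compartment",
    "CompartmentMask",
    "BoundaryPolyline",
    "StripeWidthResult",
    "load_compartments",
    "rasterize_polygons",
    "compartment_fractions",
    "stripe_width",
    "CompartmentConflictError",
    "GeometryError",
]


class CompartmentConflictError(ValueError):
    """Overlapping polygons assign different compartments to the same pixel."""


class GeometryError(ValueError):
    """Boundary polylines do not admit a width measurement."""


class Compartment(enum.IntEnum):
    """Label codes of a compartment mask raster."""

    BACKGROUND = 0
    CORTEX = 1
    OUTER_STRIPE = 2
    INNER_STRIPE = 3
    OTHER_MEDULLA = 4
    EXCLUDED = 5  # e.g. glomeruli, dropped from all analyses


MEDULLA_LABELS = (
    Compartment.OUTER_STRIPE,
    Compartment.INNER_STRIPE,
    Compartment.OTHER_MEDULLA,
)
TISSUE_LABELS = (Compartment.CORTEX,) + MEDULLA_LABELS

#: Selectors accepted by :meth:`CompartmentMask.selector_mask`.
SELECTORS = {
    "all": TISSUE_LABELS,
    "cortex": (Compartment.CORTEX,),
    "medulla": MEDULLA_LABELS,
    "outer_stripe": (Compartment.OUTER_STRIPE,),
    "inner_stripe": (Compartment.INNER_STRIPE,),
    "other_medulla": (Compartment.OTHER_MEDULLA,),
}


@dataclass
class CompartmentMask:
    """Pixel-aligned compartment label map with physical scale.

    ``labels`` holds one :class:`Compartment` code per pixel (row-major,
    0-based, pixel-center semantics); ``microns_per_pixel`` converts pixel
    measures to physical units.
    """

    labels: np.ndarray
    microns_per_pixel: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        valid = {int(c) for c in Compartment}
        found = set(np.unique(self.labels).tolist())
        unknown = found - valid
        if unknown:
            raise ValueError(f"unknown compartment codes in mask: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def selector_mask(self, compartment: str = "all") -> np.ndarray:
        """Boolean mask of the pixels belonging to a compartment selector.

        ``"all"`` is the union of cortex and medulla; excluded regions and
        background are never part of any selector.
        """
        try:
            codes = SELECTORS[compartment]
        except KeyError:
            raise ValueError(
                f"unknown compartment selector {compartment!r}; "
                f"expected one of {sorted(SELECTORS)}"
            ) from None
        return np.isin(self.labels, [int(c) for c in codes])

    def excluded_mask(self) -> np.ndarray:
        return self.labels == int(Compartment.EXCLUDED)

    def tissue_area_um2(self, compartment: str = "all") -> float:
        """Analyzable tissue area (µm²) of a compartment, exclusions omitted."""
        return float(self.selector_mask(compartment).sum()) * self.microns_per_pixel**2


@dataclass
class BoundaryPolyline:
    """An ordered, non-self-intersecting polyline in (x, y) pixel coordinates."""

    vertices: np.ndarray
    role: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of x, y coordinates")
        if len(self.vertices) < 2:
            raise ValueError("a polyline needs at least 2 vertices")
        if not self.line().is_simple:
            raise ValueError(f"polyline {self.role!r} is self-intersecting")

    def line(self) -> LineString:
        return LineString(self.vertices)


_NAME_TO_CODE = {
    "background": Compartment.BACKGROUND,
    "cortex": Compartment.CORTEX,
    "outer_stripe": Compartment.OUTER_STRIPE,
    "inner_stripe": Compartment.INNER_STRIPE,
    "other_medulla": Compartment.OTHER_MEDULLA,
    "excluded": Compartment.EXCLUDED,
    "glomerulus": Compartment.EXCLUDED,
}


def rasterize_polygons(
    polygons: list[tuple[str, np.ndarray]],
    shape: tuple[int, int],
    microns_per_pixel: float,
) -> CompartmentMask:
    """Rasterize named compartment polygons onto a label raster.

    A pixel (row i, column j) is assigned to a polygon when its center
    (x = j + 0.5, y = i + 0.5) lies strictly inside the polygon; no
    anti-aliasing.  An axis-aligned square from (0, 0) to (w, h) therefore
    covers exactly ``w * h`` pixels.  Two polygons of the same compartment
    may overlap; polygons of different compartments may not.
    """
    labels = np.zeros(shape, dtype=np.uint8)
    for name, verts in polygons:
        key = name.lower()
        if key not in _NAME_TO_CODE:
            raise ValueError(f"unknown compartment name {name!r}")
        code = int(_NAME_TO_CODE[key])
        poly = Polygon(np.asarray(verts, dtype=np.float64))
        if not poly.is_valid:
            raise ValueError(f"polygon {name!r} is not a valid simple polygon")
        minx, miny, maxx, maxy = poly.bounds
        j0 = max(int(np.floor(minx)), 0)
        j1 = min(int(np.ceil(maxx)), shape[1])
        i0 = max(int(np.floor(miny)), 0)
        i1 = min(int(np.ceil(maxy)), shape[0])
        if j1 <= j0 or i1 <= i0:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        inside = shapely.contains_xy(poly, jj + 0.5, ii + 0.5)
        sub = labels[i0:i1, j0:j1]
        conflict = inside & (sub != 0) & (sub != code)
        if conflict.any():
            rows, cols = np.nonzero(conflict)
            examples = [
                (int(r + i0), int(c + j0), Compartment(sub[r, c]).name.lower())
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise CompartmentConflictError(
                f"polygon {name!r} overlaps a different compartment at "
                f"{conflict.sum()} pixels, e.g. (row, col, existing): {examples}"
            )
        sub[inside] = code
    return CompartmentMask(labels=labels, microns_per_pixel=microns_per_pixel)


def load_compartments(
    path: str | Path,
    microns_per_pixel: float,
    shape: tuple[int, int] | None = None,
) -> CompartmentMask:
    """Load a compartment annotation from disk.

    ``.png`` files are read as integer label rasters using the documented
    code table (:class:`Compartment`).  ``.json`` / ``.geojson`` files are
    GeoJSON-style FeatureCollections of named polygons in pixel coordinates
    (property ``compartment``); ``shape`` is then required unless the file
    carries an ``image_shape`` member.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        raster = np.asarray(iio.imread(path))
        if raster.ndim == 3:
            raster = raster[..., 0]
        return CompartmentMask(labels=raster, microns_per_pixel=microns_per_pixel)
    if path.suffix.lower() in (".json", ".geojson"):
        with open(path) as fh:
            doc = json.load(fh)
        if shape is None:
            if "image_shape" not in doc:
                raise ValueError("polygon annotation needs `shape` or an image_shape member")
            shape = tuple(doc["image_shape"])
        polys = []
        for feat in doc.get("features", []):
            name = feat.get("properties", {}).get("compartment")
            if name is None:
                raise ValueError("feature missing `compartment` property")
            geom = feat.get("geometry", {})
            if geom.get("type") != "Polygon":
                raise ValueError(f"unsupported geometry type {geom.get('type')!r}")
            polys.append((name, np.asarray(geom["coordinates"][0], dtype=float)))
        return rasterize_polygons(polys, shape, microns_per_pixel)
    raise ValueError(f"unsupported annotation format: {path.suffix}")


def compartment_fractions(mask: CompartmentMask, detail: bool = False) -> dict[str, float]:
    """Percent of analyzable tissue in cortex vs. medulla.

    Percentages are taken over non-background, non-excluded pixels, so
    cortex% + medulla% = 100 whenever any tissue is present.  With
    ``detail=True`` the medullary stripes are reported as well (they sum to
    the medulla percentage).  Returns NaNs when the mask holds no tissue.
    """
    labels = mask.labels
    n_cortex = int((labels == int(Compartment.CORTEX)).sum())
    n_stripes = {
        "outer_stripe": int((labels == int(Compartment.OUTER_STRIPE)).sum()),
        "inner_stripe": int((labels == int(Compartment.INNER_STRIPE)).sum()),
        "other_medulla": int((labels == int(Compartment.OTHER_MEDULLA)).sum()),
    }
    n_medulla = sum(n_stripes.values())
    n_tissue = n_cortex + n_medulla
    if n_tissue == 0:
        out = {"cortex": float("nan"), "medulla": float("nan")}
        if detail:
            out.update({k: float("nan") for k in n_stripes})
        return out
    out = {
        "cortex": 100.0 * n_cortex / n_tissue,
        "medulla": 100.0 * n_medulla / n_tissue,
    }
    if detail:
        out.update({k: 100.0 * v / n_tissue for k, v in n_stripes.items()})
    return out


@dataclass
class StripeWidthResult:
    """Median perpendicular width between two boundaries, with sample spread."""

    width_mm: float
    distances_mm: np.ndarray = field(repr=False)
    n_samples: int = 0
    n_misses: int = 0

    @property
    def spread_mm(self) -> float:
        """Interquartile range of the sampled distances."""
        if len(self.distances_mm) == 0:
            return float("nan")
        q1, q3 = np.percentile(self.distances_mm, [25, 75])
        return float(q3 - q1)


def stripe_width(
    a: BoundaryPolyline,
    b: BoundaryPolyline,
    microns_per_pixel: float,
    sample_interval_px: float = 20.0,
) -> StripeWidthResult:
    """Digital-ruler width between two roughly parallel boundary polylines.

    Points are sampled along ``a`` at regular arc-length intervals; at each
    sample a ray is cast along the local normal (both directions) and the
    distance to the nearest intersection with ``b`` recorded.  The width is
    the median of those distances, converted to millimetres.  The median is
    robust to annotation jitter and to rays that graze ``b`` obliquely.

    Raises
    ------
    GeometryError
        If the polylines intersect each other, or if more than half the
        sampled normals never reach ``b``.
    """
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be > 0")
    if sample_interval_px <= 0:
        raise ValueError("sample_interval_px must be > 0")
    line_a = a.line()
    line_b = b.line()
    if line_a.intersects(line_b):
        raise GeometryError("boundary polylines intersect; no width is defined")

    length = line_a.length
    n = max(int(np.floor(length / sample_interval_px)) + 1, 2)
    stations = np.linspace(0.0, length, n)
    # ray long enough to cross the joint bounding box from any sample point
    ax0, ay0, ax1, ay1 = line_a.bounds
    bx0, by0, bx1, by1 = line_b.bounds
    dx = max(ax1, bx1) - min(ax0, bx0)
    dy = max(ay1, by1) - min(ay0, by0)
    reach = 2.0 * (dx + dy + 1.0)
    eps = min(1.0, length / 2.0)

    dists_px = []
    misses = 0
    for s in stations:
        p = line_a.interpolate(s)
        p0 = line_a.interpolate(max(s - eps, 0.0))
        p1 = line_a.interpolate(min(s + eps, length))
        tx, ty = p1.x - p0.x, p1.y - p0.y
        norm = np.hypot(tx, ty)
        if norm == 0:
            misses += 1
            continue
        nx, ny = -ty / norm, tx / norm
        best = np.inf
        for sgn in (1.0, -1.0):
            ray = LineString(
                [(p.x, p.y), (p.x + sgn * nx * reach, p.y + sgn * ny * reach)]
            )
            hit = ray.intersection(line_b)
            if hit.is_empty:
                continue
            d = p.distance(hit)
            best = min(best, d)
        if np.isfinite(best):
            dists_px.append(best)
        else:
            misses += 1

    if misses > 0.5 * n:
        raise GeometryError(
            f"normals from {a.role or 'boundary a'} missed "
            f"{b.role or 'boundary b'} for {misses}/{n} samples; "
            "boundaries are not roughly parallel"
        )
    dists_mm = np.asarray(dists_px) * microns_per_pixel / 1000.0
    return StripeWidthResult(
        width_mm=float(np.median(dists_mm)),
        distances_mm=dists_mm,
        n_samples=n,
        n_misses=misses,
    )
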