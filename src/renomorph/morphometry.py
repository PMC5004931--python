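"""Per-case, per-compartment metric panel.

Builds the slide-level morphometry row: stain positivity percentages per
compartment, the T-P fibrosis statistic (trichrome% minus PAS%, which
subtracts basement-membrane signal — and often proteinaceous casts — from
the fibrosis estimate), epithelial cell mass from trichrome red and averaged
cytokeratin, collagen III deposition, microvessel statistics and stripe
widths.  Missing inputs propagate as NaN columns rather than zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .color import StainProfile, classify_pixels, percent_positive
from .compartments import CompartmentMask

__all__ = [
    "quantify_stain",
    "tp_fibrosis",
    "average_cytokeratin",
    "assemble_slide_metrics",
    "SlideMetrics",
    "COMPARTMENT_PREFIX",
    "metric_column",
]

#: Column-name prefixes for the three reporting compartments.
COMPARTMENT_PREFIX = {"all": "All", "cortex": "Ctx", "medulla": "Med"}


def metric_column(compartment: str, metric: str) -> str:
    """Column name for a metric in a reporting compartment, e.g. ``Ctx-Tri``."""
    return f"{COMPARTMENT_PREFIX[compartment]}-{metric}"


def quantify_stain(
    image: np.ndarray,
    profile: StainProfile,
    mask: CompartmentMask,
    compartment: str = "all",
) -> float:
    """Percent stain-positive tissue within one compartment.

    Classification is restricted to the selected compartment with excluded
    regions (glomeruli) omitted; ``"all"`` is the union of cortex and
    medulla.  Returns NaN when the selector matches no pixels or the
    compartment holds no tissue.
    """
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image shape {image.shape[:2]} does not match mask shape {mask.shape}"
        )
    region = mask.selector_mask(compartment)
    if not region.any():
        return float("nan")
    result, _ = classify_pixels(image, profile, region, region_label=compartment)
    return percent_positive(result)


def tp_fibrosis(tri_pct: float, pas_pct: float) -> float:
    """T-P fibrosis: trichrome-positive % minus PAS-positive %.

    Negative values are meaningful (heavy basement-membrane staining can
    exceed the trichrome signal) and are preserved.  NaN in either input
    yields NaN.
    """
    if math.isnan(tri_pct) or math.isnan(pas_pct):
        return float("nan")
    return tri_pct - pas_pct


def average_cytokeratin(values: list[float]) -> float:
    """Mean of the available cytokeratin positivity percentages.

    When several cytokeratin antibodies were applied to a case, the single
    reported epithelial-mass value is their arithmetic mean.  NaN entries are
    ignored; an empty or all-NaN list yields NaN.
    """
    vals = [v for v in values if not math.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


@dataclass
class SlideMetrics:
    """One cohort-table row: all metrics measured on a single case."""

    case_id: str
    values: dict[str, float] = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        s = pd.Series(self.values, dtype=float)
        s.name = self.case_id
        return s


def assemble_slide_metrics(
    case_id: str,
    images: dict[str, np.ndarray],
    profiles: dict[str, StainProfile],
    mask: CompartmentMask,
    microvessel_results: dict[str, "object"] | None = None,
    os_width_mm: float = float("nan"),
    is_width_mm: float = float("nan"),
    visual_scores: dict[str, float] | None = None,
    creatinine: float = float("nan"),
) -> SlideMetrics:
    """Materialize one metric row from a case's stain panel.

    Parameters
    ----------
    images : dict
        Stain name -> RGB image.  Recognized stains: ``trichrome`` (quantified
        twice, with the ``trichrome_blue`` and ``trichrome_red`` profiles),
        ``pas``, ``collagen_iii``, any number of keys starting with
        ``cytokeratin`` (averaged), and ``cd34`` (used upstream for
        microvessel analysis, not quantified here).
    profiles : dict
        Stain name -> :class:`StainProfile`; must cover the stains present.
    microvessel_results : dict, optional
        Compartment selector -> ``MicrovesselResult`` (from
        :func:`renomorph.microvessel.microvessel_stats`).
    visual_scores : dict, optional
        Pre-named visual-assessment columns (e.g. ``Vis-Ctx-Tri``), passed
        through unchanged.

    Missing stains simply leave their columns (and any derived columns such
    as T-P) as NaN.
    """
    if not images:
        raise ValueError("at least one stain image is required")
    values: dict[str, float] = {}
    compartments = ("all", "cortex", "medulla")

    def quant(stain_key: str, profile_key: str, comp: str) -> float:
        img = images.get(stain_key)
        if img is None:
            return float("nan")
        return quantify_stain(img, profiles[profile_key], mask, comp)

    ck_keys = sorted(k for k in images if k.startswith("cytokeratin"))
    for comp in compartments:
        tri = quant("trichrome", "trichrome_blue", comp)
        red = quant("trichrome", "trichrome_red", comp)
        pas = quant("pas", "pas", comp)
        col = quant("collagen_iii", "collagen_iii", comp)
        ck = average_cytokeratin(
            [quantify_stain(images[k], profiles["cytokeratin"], mask, comp) for k in ck_keys]
        )
        values[metric_column(comp, "Tri")] = tri
        values[metric_column(comp, "RedTri")] = red
        values[metric_column(comp, "PAS")] = pas
        values[metric_column(comp, "T-P")] = tp_fibrosis(tri, pas)
        values[metric_column(comp, "Col")] = col
        values[metric_column(comp, "CKAvg")] = ck

    if microvessel_results:
        for comp, res in microvessel_results.items():
            values[metric_column(comp, "MVD")] = res.mvd
            values[metric_column(comp, "MVA")] = res.mva

    values["Out-Stri-mm"] = os_width_mm
    values["Inn-Stri-mm"] = is_width_mm
    if visual_scores:
        values.update({k: float(v) for k, v in visual_scores.items()})
    if not math.isnan(creatinine):
        values["Creatinine"] = creatinine
    return SlideMetrics(case_id=case_id, values=values)
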