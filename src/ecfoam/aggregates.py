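"""Aggregate morphometry, foam pore sizing and live/dead viability.

Aggregates are connected foreground components of a (thresholded) confocal
projection; each is summarized by its area in um^2 and its equivalent
diameter, the diameter of the circle of equal area. The headline summary is
the fraction and covered area of aggregates larger than a cutoff (default
300 um, the size beyond which spheroids develop hypoxic, necrotic cores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops


@dataclass
class Aggregate:
    label: int
    area_um2: float
    equivalent_diameter_um: float
    centroid: tuple[float, float]


@dataclass
class AggregationSummary:
    n_total: int
    n_large: int
    large_fraction_pct: float
    large_area_per_unit_area: float
    empty_input: bool = False


@dataclass
class ViabilityResult:
    n_live: int
    n_dead: int
    viability_pct: float


def _binarize(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype == bool:
        return image
    vals = np.unique(image)
    if len(vals) <= 2:  # already a mask
        return image > vals.min()
    return image > threshold_otsu(image.astype(float))


def label_aggregates(
    image: np.ndarray,
    pixel_size_um: float,
    min_diameter_um: float = 40.0,
) -> list[Aggregate]:
    """Measure connected foreground components in physical units.

    Grayscale input is Otsu-thresholded and hole-filled first. Components
    whose equivalent diameter falls below ``min_diameter_um`` (default 40 um,
    excluding single dispersed cells) are dropped. Touching objects merge —
    connected components, no splitting.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    mask = ndimage.binary_fill_holes(_binarize(image))
    out = []
    for prop in regionprops(cc_label(mask)):
        area_um2 = prop.area * pixel_size_um**2
        diam_um = 2.0 * np.sqrt(area_um2 / np.pi)
        if diam_um >= min_diameter_um:
            out.append(
                Aggregate(
                    label=int(prop.label),
                    area_um2=float(area_um2),
                    equivalent_diameter_um=float(diam_um),
                    centroid=tuple(prop.centroid),
                )
            )
    return out


def summarize_aggregates(
    aggregates: list[Aggregate],
    cutoff_um: float = 300.0,
    field_area_um2: float = 1.0,
) -> AggregationSummary:
    """Large-aggregate fraction and covered area per unit field area.

    "Large" means equivalent diameter strictly greater than ``cutoff_um``.
    An empty input reports 0% with ``empty_input`` set rather than failing.
    """
    if field_area_um2 <= 0:
        raise ValueError("field_area_um2 must be positive")
    n_total = len(aggregates)
    large = [a for a in aggregates if a.equivalent_diameter_um > cutoff_um]
    if n_total == 0:
        return AggregationSummary(0, 0, 0.0, 0.0, empty_input=True)
    return AggregationSummary(
        n_total=n_total,
        n_large=len(large),
        large_fraction_pct=100.0 * len(large) / n_total,
        large_area_per_unit_area=sum(a.area_um2 for a in large) / field_area_um2,
    )


def bubble_sizes(image: np.ndarray, pixel_size_um: float) -> list[float]:
    """Equivalent diameters (um) of foam pores in a binary pore mask.

    Same measurement machinery as aggregates, with no size floor.
    """
    return [
        a.equivalent_diameter_um
        for a in label_aggregates(image, pixel_size_um, min_diameter_um=0.0)
    ]


def viability(green_count: int, red_count: int) -> ViabilityResult:
    """Live/dead ratio as a percentage of total cells."""
    if green_count < 0 or red_count < 0:
        raise ValueError("counts must be nonnegative")
    total = green_count + red_count
    if total == 0:
        raise ValueError("no cells detected")
    return ViabilityResult(
        n_live=green_count,
        n_dead=red_count,
        viability_pct=100.0 * green_count / total,
    )
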