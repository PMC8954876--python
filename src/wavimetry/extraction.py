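"""Per-slice extraction of candidate lamella fragments.

A tomographic cross-section shows elastic lamellae as bright thin curves.
Extraction proceeds in three steps on each 2D slice:

1. threshold at a configurable multiple (default 2x) of the Otsu threshold
   computed on a 256-bin histogram of the min-max rescaled slice;
2. label connected components (8-connectivity by default — thin curves at
   arbitrary angles fragment under 4-connectivity);
3. keep a region iff it satisfies all three of
   ``area >= min_area`` (drops specks),
   ``bbox_occupancy < max_bbox_occupancy`` (drops patches of superimposed
   lamellae), and
   ``solidity < max_solidity`` (drops unstructured solid zones such as the
   external adventitia).

Inequality senses follow the rule wording: area is inclusive ("above or
equal"), occupancy and solidity are strict ("below" / "less than").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

log = logging.getLogger(__name__)

#: order in which filter rules are attributed to a rejected region
FILTER_RULES = ("area", "bbox_occupancy", "solidity")


@dataclass
class ImageStack:
    """Ordered grayscale slices with pixel-size metadata."""

    slices: list[np.ndarray]
    pixel_size: float = 0.65          # micrometres per pixel
    stack_id: str = "stack"
    group_label: str | None = None
    region_label: str | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"slices of {self.stack_id} differ in shape: {shapes}")


@dataclass(frozen=True)
class ExtractionParams:
    """Threshold and region-filter settings."""

    otsu_factor: float = 2.0
    min_area: int = 100
    max_bbox_occupancy: float = 0.15
    max_solidity: float = 0.36
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.otsu_factor <= 0:
            raise ValueError("otsu_factor must be > 0")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        for name in ("max_bbox_occupancy", "max_solidity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class FragmentRegion:
    """One connected bright region on one slice."""

    slice_index: int
    region_id: int
    pixel_coords: np.ndarray          # (n, 2) array of (row, col)
    area: int
    bbox: tuple[int, int, int, int]   # (min_row, min_col, height, width)
    bbox_occupancy: float
    solidity: float
    mask: np.ndarray = field(repr=False, default=None)  # cropped bool array

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.pixel_coords[:, 0], self.pixel_coords[:, 1]] = True
        return out


def rescale_to_byte(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 255] (float), the histogram convention used
    before Otsu thresholding; raises on constant images."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        raise ValueError("constant image: Otsu threshold undefined")
    return (image - lo) / (hi - lo) * 255.0


def threshold_slice(image: np.ndarray, params: ExtractionParams = ExtractionParams(),
                    ) -> np.ndarray:
    """Binary foreground mask at ``otsu_factor`` x the Otsu threshold.

    The Otsu threshold is the exhaustive between-class-variance maximizer
    over a 256-bin histogram of the rescaled slice.  A threshold above the
    image maximum yields an all-background mask with a logged warning.
    """
    scaled = rescale_to_byte(image)
    t = params.otsu_factor * threshold_otsu(scaled, nbins=256)
    if t >= scaled.max():
        log.warning("threshold %.1f above image maximum %.1f: empty mask",
                    t, scaled.max())
        return np.zeros(image.shape, dtype=bool)
    return scaled > t


def label_fragments(binary: np.ndarray,
                    params: ExtractionParams = ExtractionParams(),
                    slice_index: int = 0) -> list[FragmentRegion]:
    """Connected-component regions of a binary slice with shape descriptors.

    Convex-hull (solidity) pixel counts include pixels whose centers lie on
    the hull boundary.
    """
    conn = 1 if params.connectivity == 4 else 2
    labels = sk_label(binary, connectivity=conn)
    regions: list[FragmentRegion] = []
    for prop in regionprops(labels):
        mr, mc, xr, xc = prop.bbox
        h, w = xr - mr, xc - mc
        regions.append(FragmentRegion(
            slice_index=slice_index,
            region_id=prop.label,
            pixel_coords=prop.coords,
            area=int(prop.area),
            bbox=(mr, mc, h, w),
            bbox_occupancy=prop.area / (h * w),
            solidity=float(prop.solidity),
            mask=prop.image.copy(),
        ))
    return regions


def rejection_rule(region: FragmentRegion,
                   params: ExtractionParams = ExtractionParams()) -> str | None:
    """First filter rule the region violates (order: area, bbox_occupancy,
    solidity), or None if the region passes all three."""
    if region.area < params.min_area:
        return "area"
    if region.bbox_occupancy >= params.max_bbox_occupancy:
        return "bbox_occupancy"
    if region.solidity >= params.max_solidity:
        return "solidity"
    return None


@dataclass
class FilterResult:
    kept: list[FragmentRegion]
    rejection_counts: dict[str, int]
    reasons: list[str | None]   # aligned with the input regions

    def __iter__(self):
        # allows ``kept, counts = filter_fragments(...)`` unpacking
        yield self.kept
        yield self.rejection_counts


def filter_fragments(regions: list[FragmentRegion],
                     params: ExtractionParams = ExtractionParams(),
                     ) -> FilterResult:
    """Apply the three keep/reject rules, preserving input order.

    Returns the kept regions plus per-rule rejection counts (a rejected
    region is counted once, under the first rule it violates).  Idempotent:
    filtering an already-kept list changes nothing.
    """
    kept: list[FragmentRegion] = []
    counts = {rule: 0 for rule in FILTER_RULES}
    reasons: list[str | None] = []
    for region in regions:
        rule = rejection_rule(region, params)
        reasons.append(rule)
        if rule is None:
            kept.append(region)
        else:
            counts[rule] += 1
    return FilterResult(kept=kept, rejection_counts=counts, reasons=reasons)


def extract_fragments(image: np.ndarray,
                      params: ExtractionParams = ExtractionParams(),
                      slice_index: int = 0, binary_input: bool = False,
                      ) -> FilterResult:
    """Threshold (unless already binary), label, and filter one slice."""
    if binary_input:
        binary = np.asarray(image) > 0
    else:
        binary = threshold_slice(image, params)
    regions = label_fragments(binary, params, slice_index=slice_index)
    return filter_fragments(regions, params)
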