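"""Analyzable-tissue detection, exclusion ROIs, and physical area.

Tissue is detected by Gaussian-blurring the autofluorescence channel and
thresholding it (Otsu by default, or a manual cutoff), followed by removal
of small components — the automated analogue of excluding non-tissue
whitespace.  Manual exclusions (staining artifacts, non-renal tissue, folds)
enter as GeoJSON polygon ROIs and are subtracted from the mask.

Coordinate conventions: pixel coordinates are 0-based (row, col) with the
origin at the top-left; GeoJSON/shapely polygons use (x, y) = (col, row).
Rasterization includes exactly the pixels whose centers fall strictly
inside the polygon, which makes area arithmetic in tests exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
import tifffile
from scipy import ndimage as ndi
from shapely.geometry import Polygon, shape as geo_shape, mapping as geo_mapping
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .stack import ChannelStack


@dataclass
class TissueMask:
    """Binary analyzable-tissue mask with provenance.

    ``provenance`` is an append-only list of parameter records, one per
    operation that produced or modified the mask.
    """

    mask: np.ndarray
    pixel_size_um: float
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def area_mm2(self) -> float:
        return mask_area_mm2(self)

    def write_tiff(self, path) -> None:
        """0/255 single-page 8-bit TIFF."""
        tifffile.imwrite(path, (self.mask.astype(np.uint8) * 255))


@dataclass(frozen=True)
class ExclusionRoi:
    """Polygonal region removed from analysis, with a reason tag."""

    id: str
    polygon: Polygon
    reason: str = "other"

    REASONS = ("whitespace", "artifact", "non_renal", "other")

    def __post_init__(self) -> None:
        if self.reason not in self.REASONS:
            raise ValueError(f"reason must be one of {self.REASONS}")
        if not self.polygon.is_valid:
            raise ValueError(f"ROI {self.id!r}: polygon must be closed and simple")


def compute_tissue_mask(stack: ChannelStack, af_channel: str = "AF",
                        blur_sigma: float = 4.0, method: str = "otsu",
                        manual_threshold: float | None = None,
                        min_component_px: int = 500) -> TissueMask:
    """Detect tissue on the blurred autofluorescence channel.

    Parameters
    ----------
    blur_sigma
        Gaussian sigma in pixels applied before thresholding.
    method
        ``"otsu"`` (between-class variance maximum) or ``"manual"``
        (requires ``manual_threshold``).  The mask is true where the
        blurred intensity is >= the threshold.
    min_component_px
        Connected components smaller than this are dropped (automated
        whitespace/speck removal).  Set 0 to keep everything.
    """
    af = np.asarray(stack.channel(af_channel), dtype=float)
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    blurred = ndi.gaussian_filter(af, blur_sigma) if blur_sigma > 0 else af

    if method == "manual":
        if manual_threshold is None:
            raise ValueError("manual_threshold is required when method='manual'")
        threshold = float(manual_threshold)
        mask = blurred >= threshold
    elif method == "otsu":
        if np.ptp(blurred) == 0:  # zero-variance guard: constant channel
            threshold = float("inf")
            mask = np.zeros_like(blurred, dtype=bool)
        else:
            threshold = float(threshold_otsu(blurred))
            mask = blurred >= threshold
    else:
        raise ValueError(f"unknown method {method!r}; use 'otsu' or 'manual'")

    if min_component_px > 0 and mask.any():
        mask = remove_small_objects(mask, max_size=min_component_px - 1)

    return TissueMask(
        mask, stack.pixel_size_um,
        provenance=[{
            "op": "compute_tissue_mask", "af_channel": af_channel,
            "blur_sigma": blur_sigma, "method": method,
            "threshold": threshold, "min_component_px": min_component_px,
        }],
    )


def rasterize_polygon(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Pixels of ``shape`` whose centers fall strictly inside ``poly``.

    The polygon is clipped to the image bounds implicitly.
    """
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
    r0, r1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
    if c1 < c0 or r1 < r0:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.contains_xy(poly, cols.ravel().astype(float),
                                 rows.ravel().astype(float))
    mask[r0:r1 + 1, c0:c1 + 1] = inside.reshape(rows.shape)
    return mask


def apply_exclusions(mask: TissueMask, rois: list[ExclusionRoi]) -> TissueMask:
    """Subtract the union of rasterized ROIs from the mask.

    An empty ROI list is the identity; applying the same ROI twice is
    idempotent; exclusions never increase the area.
    """
    out = mask.mask.copy()
    for roi in rois:
        out &= ~rasterize_polygon(roi.polygon, out.shape)
    prov = list(mask.provenance)
    prov.append({
        "op": "apply_exclusions",
        "roi_ids": [roi.id for roi in rois],
        "reasons": [roi.reason for roi in rois],
    })
    return TissueMask(out, mask.pixel_size_um, prov)


def mask_area_mm2(mask: TissueMask) -> float:
    """True-pixel count x (pixel_size_um / 1000)^2, in mm^2."""
    px_mm = mask.pixel_size_um / 1000.0
    return float(mask.mask.sum()) * px_mm * px_mm


# ---------------------------------------------------------------------------
# GeoJSON round-trip for exclusion ROIs


def read_rois_geojson(path) -> list[ExclusionRoi]:
    with open(path) as fh:
        fc = json.load(fh)
    rois = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties") or {}
        rois.append(ExclusionRoi(
            id=str(props.get("id", f"roi-{i}")),
            polygon=geo_shape(feat["geometry"]),
            reason=props.get("reason", "other"),
        ))
    return rois


def write_rois_geojson(rois: list[ExclusionRoi], path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": geo_mapping(roi.polygon),
                "properties": {"id": roi.id, "reason": roi.reason},
            }
            for roi in rois
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh, indent=1)
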