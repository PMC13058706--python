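"""Per-cell instance label masks: built-in classical segmenter or external.

The built-in segmenter is a deterministic watershed pipeline on the nuclear
channel (smooth -> Otsu foreground -> distance transform -> peak-seeded
watershed -> small-object removal).  It is intentionally classical: any
external instance-segmentation tool (e.g. a pretrained neural model) can be
substituted by loading its integer label mask, and everything downstream is
agnostic to the source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .stack import ChannelStack


@dataclass
class LabelMask:
    """Integer cell-instance map; 0 = background, labels need not be contiguous."""

    labels: np.ndarray
    source: str = "builtin"  # "builtin" | "external"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(f"label mask must be integer-typed, got {self.labels.dtype}")
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_cells(self) -> int:
        return int(self.ids.size)

    def write_tiff(self, path) -> None:
        dtype = np.uint16 if self.labels.max(initial=0) < 2 ** 16 else np.uint32
        tifffile.imwrite(path, self.labels.astype(dtype))


def segment_nuclei(stack: ChannelStack, dapi_channel: str = "DAPI",
                   smooth_sigma: float = 1.0, min_area_px: int = 20,
                   min_peak_distance_px: int = 5) -> LabelMask:
    """Watershed nuclei segmentation on the DAPI channel.

    Touching nuclei are split at distance-transform peaks at least
    ``min_peak_distance_px`` apart; components smaller than ``min_area_px``
    are removed.  Seeds are numbered in (row, col) scan order so the result
    is platform-stable.
    """
    if min_area_px <= 0 or min_peak_distance_px <= 0 or smooth_sigma < 0:
        raise ValueError("segmentation parameters must be positive")
    dapi = np.asarray(stack.channel(dapi_channel), dtype=float)
    smoothed = ndi.gaussian_filter(dapi, smooth_sigma) if smooth_sigma > 0 else dapi

    if np.ptp(smoothed) == 0:  # blank channel: no foreground
        return LabelMask(np.zeros(smoothed.shape, dtype=np.int32), "builtin")
    # Otsu on log intensity: nuclear brightness is right-skewed (lognormal-
    # like), so a raw-scale split can sit above the dimmest nuclei.
    log_img = np.log1p(np.maximum(smoothed, 0.0))
    fg = log_img >= threshold_otsu(log_img)
    if not fg.any():
        return LabelMask(np.zeros(smoothed.shape, dtype=np.int32), "builtin")

    distance = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        distance, min_distance=min_peak_distance_px,
        labels=cc_label(fg, connectivity=1), exclude_border=False,
    )
    if len(peaks) == 0:
        return LabelMask(np.zeros(smoothed.shape, dtype=np.int32), "builtin")
    # deterministic seed ids: lexicographic (row, col) order
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    peaks = peaks[order]
    markers = np.zeros(smoothed.shape, dtype=np.int32)
    markers[peaks[:, 0], peaks[:, 1]] = np.arange(1, len(peaks) + 1)

    labels = watershed(-distance, markers, mask=fg, connectivity=1)

    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area_px)
    small = small[small > 0]
    if small.size:
        labels[np.isin(labels, small)] = 0
    return LabelMask(labels.astype(np.int32), "builtin")


def expand_labels(mask: LabelMask, radius_px: int) -> LabelMask:
    """Grow every label by up to ``radius_px`` without overlap.

    Background pixels are claimed by the nearest label within Euclidean
    distance ``radius_px``; exact ties go to the smaller label id.  Original
    label pixels are never reassigned and the label set is unchanged.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    labels = mask.labels
    if radius_px == 0 or mask.n_cells == 0:
        return LabelMask(labels.copy(), mask.source)

    out = labels.copy()
    h, w = labels.shape
    best = np.full(labels.shape, np.inf)
    best[labels > 0] = 0.0
    objects = ndi.find_objects(labels)
    for lab in sorted(int(i) for i in mask.ids):
        sl = objects[lab - 1]
        if sl is None:
            continue
        r0 = max(0, sl[0].start - radius_px)
        r1 = min(h, sl[0].stop + radius_px)
        c0 = max(0, sl[1].start - radius_px)
        c1 = min(w, sl[1].stop + radius_px)
        window = (slice(r0, r1), slice(c0, c1))
        dist = ndi.distance_transform_edt(labels[window] != lab)
        claim = (dist <= radius_px) & (dist < best[window])
        out[window][claim] = lab
        best[window][claim] = dist[claim]
    return LabelMask(out, mask.source)


def load_label_mask(path, expected_shape: tuple[int, int] | None = None) -> LabelMask:
    """Ingest an external integer label mask from a single-page TIFF."""
    arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(
            f"label mask {path} must have an integer pixel type, got {arr.dtype}"
        )
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise ValueError(
            f"label mask shape {tuple(arr.shape)} does not match expected "
            f"shape {tuple(expected_shape)}"
        )
    return LabelMask(arr.astype(np.int32), "external")
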