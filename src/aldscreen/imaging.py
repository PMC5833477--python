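"""Nuclei segmentation and per-cell reporter intensity measurement.

The segmentation recipe is deliberately plain and reproducible: Gaussian
smooth (sigma = 2 px) -> Otsu threshold -> fill holes -> distance-transform
watershed seeded by h-maxima (h = 10% of the maximum distance), then area
gating. "Cellular" reporter intensity is measured on the nucleus dilated by
a cytoplasmic ring (default 3 µm; the Aldefluor product is cytoplasmic, so a
nuclear-only readout would underestimate the signal), with ring collisions
resolved by nearest-label assignment and a single scalar field background
(median of non-cell pixels) subtracted and the result floored at 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import expand_labels, relabel_sequential, watershed

log = logging.getLogger(__name__)

#: default area gates at 0.65 µm/px
DEFAULT_MIN_AREA = 30
DEFAULT_MAX_AREA = 3000
DEFAULT_RING_UM = 3.0


@dataclass
class FieldImage:
    """A two-channel field: nuclear stain + reporter, with pixel size in µm."""

    nuclear: np.ndarray
    reporter: np.ndarray
    pixel_size: float  # µm / pixel

    def __post_init__(self) -> None:
        self.nuclear = np.asarray(self.nuclear, dtype=float)
        self.reporter = np.asarray(self.reporter, dtype=float)
        if self.nuclear.shape != self.reporter.shape:
            raise ValueError("nuclear and reporter channels must have the same shape")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0 (µm/pixel)")

    @classmethod
    def from_stack(cls, stack: np.ndarray, pixel_size: float) -> "FieldImage":
        """Build from a (2, H, W) stack in (nuclear, reporter) channel order."""
        if stack.ndim != 3 or stack.shape[0] != 2:
            raise ValueError("expected a (2, H, W) channel-first stack")
        return cls(nuclear=stack[0], reporter=stack[1], pixel_size=pixel_size)


def segment_nuclei(
    img: FieldImage,
    min_area: int = DEFAULT_MIN_AREA,
    max_area: int = DEFAULT_MAX_AREA,
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """Segment nuclei from the nuclear channel into a dense label mask.

    Touching nuclei are split by a distance-transform watershed seeded at
    h-maxima of the distance map (h = 10% of its maximum). Regions outside
    [min_area, max_area] px^2 are discarded and labels relabeled densely
    from 1. An all-constant image yields an empty mask with a warning.
    """
    chan = img.nuclear
    if chan.size == 0:
        raise ValueError("empty nuclear channel")
    if np.ptp(chan) == 0:
        warnings.warn("constant nuclear channel: no nuclei segmented", stacklevel=2)
        return np.zeros(chan.shape, dtype=np.int32)

    smoothed = gaussian(chan, sigma=smooth_sigma, preserve_range=True)
    thr = threshold_otsu(smoothed)
    mask = ndi.binary_fill_holes(smoothed > thr)
    if not mask.any():
        return np.zeros(chan.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask)
    h = 0.1 * float(distance.max())
    seeds_mask = h_maxima(distance, h) if h > 0 else distance > 0
    seeds, _ = ndi.label(seeds_mask)
    labels = watershed(-distance, markers=seeds, mask=mask)

    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < min_area) | (areas > max_area))
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def _cell_regions(labels: np.ndarray, ring_px: float) -> np.ndarray:
    """Nuclear labels dilated by the cytoplasmic ring; collisions go to the
    nearest label (Euclidean), which is exactly what expand_labels does."""
    return expand_labels(labels, distance=ring_px)


def estimate_background(
    img: FieldImage, labels: np.ndarray, ring_um: float = DEFAULT_RING_UM
) -> float:
    """Median reporter intensity over pixels outside all dilated cell regions.

    Returns 0 with a warning when no unlabeled pixels remain.
    """
    expanded = _cell_regions(labels, ring_um / img.pixel_size)
    outside = expanded == 0
    if not outside.any():
        warnings.warn("no background pixels outside cell regions; background = 0",
                      stacklevel=2)
        return 0.0
    return float(np.median(img.reporter[outside]))


def measure_cells(
    img: FieldImage,
    labels: np.ndarray,
    ring_um: float = DEFAULT_RING_UM,
    well: str = "",
    background: float | None = None,
) -> pd.DataFrame:
    """Measure per-cell mean reporter intensity over nucleus + cytoplasmic ring.

    Returns one row per label with columns
    ``well,cell_id,x,y,nuc_area_px,intensity,label`` (``label`` is left
    empty: ground-truth class labels only exist for synthetic data). The
    reporter mean is background-corrected (scalar field background, see
    :func:`estimate_background`) and floored at 0.
    """
    if labels.shape != img.reporter.shape:
        raise ValueError("label mask must be aligned with the image")
    n = int(labels.max())
    if n == 0:
        return pd.DataFrame(
            columns=["well", "cell_id", "x", "y", "nuc_area_px", "intensity", "label"]
        )
    if background is None:
        background = estimate_background(img, labels, ring_um)

    regions = _cell_regions(labels, ring_um / img.pixel_size)
    idx = np.arange(1, n + 1)
    means = ndi.mean(img.reporter, labels=regions, index=idx)
    centroids = np.array(ndi.center_of_mass(np.ones_like(labels), labels, idx))
    nuc_areas = ndi.sum_labels(np.ones_like(labels), labels, idx)
    intensity = np.maximum(np.asarray(means) - background, 0.0)
    return pd.DataFrame(
        {
            "well": well,
            "cell_id": idx,
            "x": centroids[:, 1],
            "y": centroids[:, 0],
            "nuc_area_px": nuc_areas,
            "intensity": intensity,
            "label": "",
        }
    )
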