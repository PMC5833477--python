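"""Tumorsphere detection and tumorsphere-formation capacity (TFC).

Day-7 sphere images are segmented (smooth -> Otsu -> fill holes -> label),
each object is measured in micrometres, and the assay's morphometric filters
are applied: equivalent circular diameter between 50 and 250 µm (inclusive)
and shape factor (circularity, 4*pi*A/P^2) >= 0.5. Perimeters use the
Crofton approximation, which is accurate for smooth convex shapes; the
resulting discretization error on the shape factor is below ~0.05 for
objects larger than a few pixels, so an ideal circle can score slightly
above 1. Objects touching the image border are excluded (their area and
perimeter are truncated).

TFC = passing-sphere count / seeded single-cell count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops

D_MIN_UM = 50.0
D_MAX_UM = 250.0
SF_MIN = 0.5


@dataclass(frozen=True)
class SphereRecord:
    """One detected object with its morphometrics and filter outcome."""

    sphere_id: int
    area_um2: float
    perimeter_um: float
    equivalent_diameter_um: float
    shape_factor: float
    centroid_px: tuple[float, float]
    passes_filters: bool
    well: str = ""


@dataclass(frozen=True)
class TFCSummary:
    well: str
    n_spheres_pass: int
    n_seeded: int
    tfc: float
    tfc_relative: Optional[float] = None  # percent of reference
    reference_undefined: bool = False


def detect_spheres(
    image: np.ndarray,
    pixel_size: float,
    d_min: float = D_MIN_UM,
    d_max: float = D_MAX_UM,
    sf_min: float = SF_MIN,
    smooth_sigma: float = 1.0,
    well: str = "",
) -> list[SphereRecord]:
    """Detect and filter tumorspheres in a single-channel image.

    An object passes when d_min <= equivalent diameter <= d_max (µm) and
    shape factor >= sf_min, boundaries inclusive. Blank images return an
    empty list.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0 (µm/pixel)")
    if not d_min < d_max:
        raise ValueError("d_min must be < d_max")
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return []
    smoothed = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    mask = ndi.binary_fill_holes(smoothed > threshold_otsu(smoothed))
    labels = cc_label(mask)

    h, w = labels.shape
    records: list[SphereRecord] = []
    sphere_id = 0
    for region in regionprops(labels):
        minr, minc, maxr, maxc = region.bbox
        if minr == 0 or minc == 0 or maxr == h or maxc == w:
            continue  # border-touching: truncated area/perimeter
        area_um2 = region.area * pixel_size**2
        perimeter_um = region.perimeter_crofton * pixel_size
        if perimeter_um == 0:
            continue
        eq_diam = 2.0 * np.sqrt(area_um2 / np.pi)
        sf = 4.0 * np.pi * area_um2 / perimeter_um**2
        passes = (d_min <= eq_diam <= d_max) and (sf >= sf_min)
        records.append(
            SphereRecord(
                sphere_id=sphere_id,
                area_um2=float(area_um2),
                perimeter_um=float(perimeter_um),
                equivalent_diameter_um=float(eq_diam),
                shape_factor=float(sf),
                centroid_px=(float(region.centroid[1]), float(region.centroid[0])),
                passes_filters=bool(passes),
                well=well,
            )
        )
        sphere_id += 1
    return records


def compute_tfc(
    spheres: list[SphereRecord],
    n_seeded: int,
    reference_tfc: Optional[float] = None,
    well: str = "",
) -> TFCSummary:
    """TFC = passing spheres / seeded cells; optionally percent of a reference.

    ``n_seeded`` comes from the Day-0 nuclear count when Day-0 images exist,
    otherwise from the declared seeding density (100 or 200 cells/well).
    A zero reference leaves ``tfc_relative`` undefined and flags it.
    """
    if n_seeded < 1:
        raise ValueError("n_seeded must be >= 1")
    n_pass = sum(1 for s in spheres if s.passes_filters)
    tfc = n_pass / n_seeded
    tfc_relative = None
    undefined = False
    if reference_tfc is not None:
        if reference_tfc == 0:
            undefined = True
        else:
            tfc_relative = 100.0 * tfc / reference_tfc
    return TFCSummary(
        well=well,
        n_spheres_pass=n_pass,
        n_seeded=n_seeded,
        tfc=tfc,
        tfc_relative=tfc_relative,
        reference_undefined=undefined,
    )
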