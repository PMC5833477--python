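"""Synthetic fixtures with exact ground truth.

Generates the artifacts every downstream stage consumes: per-cell reporter
intensity tables drawn from a two-population (background vs. ALDH-bright)
mixture, two-channel field images with scattered nuclei, tumorsphere images
of known diameter and shape, full 384-well plates with control layouts, and
noisy 4PL dose-response curves. Ground truth is returned alongside every
artifact so tests never re-derive it from the data.

Randomness: each generator takes a single integer seed. Plate generation
splits its seed into per-well substreams via
``numpy.random.SeedSequence((seed, well_index))`` with the 0-based row-major
well index, so any single well is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage as ndi
from scipy.special import ellipe

from aldscreen.dose_response import four_pl
from aldscreen.wells import validate_well, well_names_384, PLATEMAP_COLUMNS

CELL_TABLE_COLUMNS = ["well", "cell_id", "x", "y", "nuc_area_px", "intensity", "label"]

_MAX_PLACEMENT_RETRIES = 10_000


class PlacementError(RuntimeError):
    """Could not place the requested number of objects at the requested separation."""


class MixtureSpec(BaseModel):
    """Two-population single-cell reporter intensity mixture.

    Background cells draw from Normal(bg_mean, bg_sd); bright cells from
    Normal(bg_mean + high_shift*bg_sd, high_sd). Both are truncated at zero
    by resampling (fluorescence is non-negative). ``high_sd`` defaults to
    half the background SD, giving the crisp bimodality of an Aldefluor
    histogram: at the default 8-sigma shift fewer than 0.01% of bright
    cells fall below a 6-sigma gate.
    """

    n_cells: int = Field(ge=0, default=2000)
    bg_mean: float = 100.0
    bg_sd: float = Field(gt=0, default=10.0)
    high_fraction: float = Field(ge=0.0, le=1.0, default=0.05)
    high_shift: float = Field(ge=0.0, default=8.0)
    high_sd: Optional[float] = Field(gt=0, default=None)
    seed: int = 0

    @property
    def high_mean(self) -> float:
        return self.bg_mean + self.high_shift * self.bg_sd

    @property
    def high_sd_value(self) -> float:
        return self.high_sd if self.high_sd is not None else 0.5 * self.bg_sd


class FieldImageSpec(BaseModel):
    """One imaged field: nuclei scattered at a minimum separation.

    ``nucleus_radius_um`` / ``nucleus_radius_sd_um`` give the mean and SD of
    nuclear radii in micrometres; ``cyto_ring_um`` is the cytoplasmic annulus
    over which the reporter signal is painted around each nucleus.
    """

    width: int = Field(gt=0, default=512)
    height: int = Field(gt=0, default=512)
    pixel_size: float = Field(gt=0, default=0.65)  # µm / pixel
    n_nuclei: int = Field(ge=0, default=100)
    nucleus_radius_um: float = Field(gt=0, default=6.0)
    nucleus_radius_sd_um: float = Field(ge=0, default=0.5)
    min_separation_um: float = Field(ge=0, default=18.0)
    cyto_ring_um: float = Field(ge=0, default=4.0)
    psf_sigma: float = Field(ge=0, default=1.0)  # pixels
    noise_sd: float = Field(ge=0, default=2.0)
    nuclear_intensity: float = Field(gt=0, default=600.0)
    mixture: MixtureSpec = MixtureSpec()


class SphereSpec(BaseModel):
    """One tumorsphere: equivalent circular diameter and axis elongation."""

    diameter_um: float = Field(gt=0)
    elongation: float = Field(ge=1.0, default=1.0)
    center: Optional[tuple[float, float]] = None  # (x, y) pixels
    angle_deg: float = 0.0


class SphereImageSpec(BaseModel):
    width: int = Field(gt=0, default=1024)
    height: int = Field(gt=0, default=1024)
    pixel_size: float = Field(gt=0, default=1.3)  # µm / pixel (10x widefield scale)
    spheres: list[SphereSpec] = Field(default_factory=list)
    debris_count: int = Field(ge=0, default=0)
    foreground: float = Field(gt=0, default=800.0)
    noise_sd: float = Field(ge=0, default=3.0)
    seed: int = 0


class PlateSpec(BaseModel):
    """A full 384-well plate built from a base mixture plus per-well overrides.

    ``layout`` maps well id to role (sample|dmso|deab|lipid|sirna_control|
    empty). Full-effect control roles (deab, sirna_control) force
    high_fraction to 0 — the inhibitor abolishes reporter retention —
    unless an explicit override says otherwise. ``toxicity`` multiplies a
    well's cell count (compound kills cells); ``compounds`` maps well to
    (compound name, dose in µM).
    """

    plate_format: int = 384
    layout: dict[str, str] = Field(default_factory=dict)
    base_mixture: MixtureSpec = MixtureSpec()
    overrides: dict[str, dict] = Field(default_factory=dict)
    compounds: dict[str, tuple[str, float]] = Field(default_factory=dict)
    toxicity: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PlateSpec":
        if self.plate_format != 384:
            raise ValueError("plate_format: only 384-well plates are supported")
        for well in self.layout:
            validate_well(well)
        for well, mult in self.toxicity.items():
            if mult < 0:
                raise ValueError(f"toxicity[{well}]: multiplier must be >= 0")
        return self


@dataclass
class GroundTruth:
    """Exact ground truth serialized next to every generated artifact."""

    labels: Optional[np.ndarray] = None          # per-cell "high"/"low"
    true_high_fraction: Optional[float] = None   # realized fraction in the draw
    per_well_fraction: Optional[dict] = None
    per_well_labels: Optional[dict] = None
    centers_px: Optional[np.ndarray] = None
    radii_px: Optional[np.ndarray] = None
    intensities: Optional[np.ndarray] = None
    nuclear_mask: Optional[np.ndarray] = None
    spheres: Optional[pd.DataFrame] = None
    four_pl: Optional[dict] = None

    def to_json(self, path: str | Path) -> None:
        """Write the scalar/tabular parts as a sidecar JSON (arrays as lists)."""
        payload: dict = {}
        if self.labels is not None:
            payload["labels"] = list(map(str, self.labels))
        if self.true_high_fraction is not None:
            payload["true_high_fraction"] = self.true_high_fraction
        if self.per_well_fraction is not None:
            payload["per_well_fraction"] = self.per_well_fraction
        if self.centers_px is not None:
            payload["centers_px"] = np.asarray(self.centers_px).tolist()
        if self.radii_px is not None:
            payload["radii_px"] = np.asarray(self.radii_px).tolist()
        if self.intensities is not None:
            payload["intensities"] = np.asarray(self.intensities).tolist()
        if self.spheres is not None:
            payload["spheres"] = self.spheres.to_dict(orient="records")
        if self.four_pl is not None:
            payload["four_pl"] = self.four_pl
        Path(path).write_text(json.dumps(payload, indent=1))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 by resampling (keeps moments near nominal)."""
    out = rng.normal(mean, sd, size=n)
    for _ in range(1000):
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, size=int(neg.sum()))
    out[out < 0] = 0.0
    return out


def gen_intensity_table(
    spec: MixtureSpec, well: str = "A01", field_size_px: int = 2048
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a per-cell intensity table from a two-population mixture.

    Returns a table with columns ``well,cell_id,x,y,nuc_area_px,intensity,label``
    and the ground truth (labels and the realized high fraction). Same seed,
    same table, bit for bit.
    """
    return _gen_table_with_seedseq(spec, np.random.SeedSequence(spec.seed), well)


def _place_points(
    rng: np.random.Generator,
    n: int,
    width: int,
    height: int,
    margin: float,
    min_sep_px: float,
) -> np.ndarray:
    """Rejection-sample n points with pairwise separation >= min_sep_px.

    Raises :class:`PlacementError` after a bounded number of retries per
    point rather than silently under-placing.
    """
    pts: list[tuple[float, float]] = []
    placed = np.empty((0, 2))
    for _ in range(n):
        for attempt in range(_MAX_PLACEMENT_RETRIES):
            cand = np.array(
                [rng.uniform(margin, width - margin), rng.uniform(margin, height - margin)]
            )
            if placed.shape[0] == 0 or np.min(
                np.hypot(*(placed - cand).T)
            ) >= min_sep_px:
                pts.append(tuple(cand))
                placed = np.asarray(pts)
                break
        else:
            raise PlacementError(
                f"could not place nucleus {len(pts) + 1}/{n} at separation "
                f"{min_sep_px:.1f} px after {_MAX_PLACEMENT_RETRIES} retries"
            )
    return placed.reshape(n, 2)


def _paint_disks(shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray,
                 values: np.ndarray) -> np.ndarray:
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cx, cy), r, v in zip(centers, radii, values):
        x0, x1 = int(max(0, cx - r - 2)), int(min(shape[1], cx + r + 3))
        y0, y1 = int(max(0, cy - r - 2)), int(min(shape[0], cy + r + 3))
        sub = (xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2 <= r**2
        np.maximum(img[y0:y1, x0:x1], np.where(sub, v, 0.0), out=img[y0:y1, x0:x1])
    return img


def gen_nuclei_field(spec: FieldImageSpec, well: str = "A01") -> tuple[np.ndarray, GroundTruth]:
    """Render a two-channel field: nuclei (channel 0) and reporter (channel 1).

    Nuclei are disks of per-cell radius, Gaussian-blurred by the PSF with
    additive read noise; the reporter channel paints each cell's mixture
    intensity over its nucleus plus cytoplasmic annulus. The returned ground
    truth carries centers, radii, labels, painted intensities and the
    noise-free nuclear mask.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.mixture.seed))
    shape = (spec.height, spec.width)
    n = spec.n_nuclei
    mix = spec.mixture

    r_mean_px = spec.nucleus_radius_um / spec.pixel_size
    r_sd_px = spec.nucleus_radius_sd_um / spec.pixel_size
    ring_px = spec.cyto_ring_um / spec.pixel_size
    sep_px = spec.min_separation_um / spec.pixel_size

    if n == 0:
        nuclear = rng.normal(0, spec.noise_sd, shape).clip(min=0)
        reporter = rng.normal(0, spec.noise_sd, shape).clip(min=0)
        truth = GroundTruth(
            labels=np.array([], dtype=object),
            true_high_fraction=0.0,
            centers_px=np.empty((0, 2)),
            radii_px=np.empty(0),
            intensities=np.empty(0),
            nuclear_mask=np.zeros(shape, dtype=bool),
        )
        return np.stack([nuclear, reporter]), truth

    margin = r_mean_px + ring_px + 3 * r_sd_px + 2
    centers = _place_points(rng, n, spec.width, spec.height, margin, sep_px)
    radii = np.clip(rng.normal(r_mean_px, r_sd_px, n), 1.0, None)

    labels = np.where(rng.random(n) < mix.high_fraction, "high", "low")
    intensities = np.empty(n)
    low = labels == "low"
    intensities[low] = _truncated_normal(rng, mix.bg_mean, mix.bg_sd, int(low.sum()))
    intensities[~low] = _truncated_normal(
        rng, mix.high_mean, mix.high_sd_value, int((~low).sum())
    )

    nuclear_clean = _paint_disks(shape, centers, radii, np.full(n, spec.nuclear_intensity))
    reporter_clean = _paint_disks(shape, centers, radii + ring_px, intensities)

    if spec.psf_sigma > 0:
        nuclear_img = ndi.gaussian_filter(nuclear_clean, spec.psf_sigma)
        reporter_img = ndi.gaussian_filter(reporter_clean, spec.psf_sigma)
    else:
        nuclear_img, reporter_img = nuclear_clean.copy(), reporter_clean.copy()
    if spec.noise_sd > 0:
        nuclear_img = (nuclear_img + rng.normal(0, spec.noise_sd, shape)).clip(min=0)
        reporter_img = (reporter_img + rng.normal(0, spec.noise_sd, shape)).clip(min=0)

    truth = GroundTruth(
        labels=labels,
        true_high_fraction=float((labels == "high").mean()),
        centers_px=centers,
        radii_px=radii,
        intensities=intensities,
        nuclear_mask=nuclear_clean > 0,
    )
    return np.stack([nuclear_img, reporter_img]), truth


def _ellipse_axes(diameter_um: float, elongation: float) -> tuple[float, float]:
    """Semi-axes (µm) of an ellipse with given equivalent circular diameter."""
    r = diameter_um / 2.0
    return r * np.sqrt(elongation), r / np.sqrt(elongation)


def ellipse_shape_factor(diameter_um: float, elongation: float) -> float:
    """Exact circularity 4*pi*A/P^2 of the rendered ellipse (numeric perimeter)."""
    a, b = _ellipse_axes(diameter_um, elongation)
    area = np.pi * a * b
    m = 1.0 - (b / a) ** 2
    perimeter = 4.0 * a * ellipe(m)
    return float(4.0 * np.pi * area / perimeter**2)


def _paint_ellipse(img: np.ndarray, cx: float, cy: float, a_px: float, b_px: float,
                   angle_deg: float, value: float) -> None:
    theta = np.deg2rad(angle_deg)
    ct, st = np.cos(theta), np.sin(theta)
    ext = max(a_px, b_px) + 2
    x0, x1 = int(max(0, cx - ext)), int(min(img.shape[1], cx + ext + 1))
    y0, y1 = int(max(0, cy - ext)), int(min(img.shape[0], cy + ext + 1))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    img[y0:y1, x0:x1][inside] = value


def gen_sphere_field(spec: SphereImageSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a Day-7 tumorsphere image with known diameters and shape factors.

    Spheres are filled ellipses with the requested equivalent circular
    diameter and elongation; debris objects are rendered below 50 µm.
    Ground truth records each sphere's true diameter and exact (continuous)
    shape factor.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    img = np.zeros((spec.height, spec.width))
    records = []
    occupied: list[tuple[float, float, float]] = []  # (cx, cy, clearance px)

    def _auto_center(radius_px: float) -> tuple[float, float]:
        for _ in range(_MAX_PLACEMENT_RETRIES):
            cx = rng.uniform(radius_px + 4, spec.width - radius_px - 4)
            cy = rng.uniform(radius_px + 4, spec.height - radius_px - 4)
            if all(np.hypot(cx - ox, cy - oy) > radius_px + orad + 4
                   for ox, oy, orad in occupied):
                return cx, cy
        raise PlacementError("could not place sphere without overlap")

    for i, s in enumerate(spec.spheres):
        a_um, b_um = _ellipse_axes(s.diameter_um, s.elongation)
        a_px, b_px = a_um / spec.pixel_size, b_um / spec.pixel_size
        if s.center is None:
            cx, cy = _auto_center(max(a_px, b_px))
        else:
            cx, cy = s.center
        _paint_ellipse(img, cx, cy, a_px, b_px, s.angle_deg, spec.foreground)
        occupied.append((cx, cy, max(a_px, b_px)))
        records.append(
            {
                "sphere_id": i,
                "diameter_um": s.diameter_um,
                "elongation": s.elongation,
                "shape_factor": ellipse_shape_factor(s.diameter_um, s.elongation),
                "cx": cx,
                "cy": cy,
                "is_debris": False,
            }
        )
    for j in range(spec.debris_count):
        d_um = rng.uniform(8.0, 35.0)  # well under the 50 µm size filter
        r_px = d_um / 2 / spec.pixel_size
        cx, cy = _auto_center(r_px)
        _paint_ellipse(img, cx, cy, r_px, r_px, 0.0, spec.foreground)
        occupied.append((cx, cy, r_px))
        records.append(
            {
                "sphere_id": len(spec.spheres) + j,
                "diameter_um": d_um,
                "elongation": 1.0,
                "shape_factor": 1.0,
                "cx": cx,
                "cy": cy,
                "is_debris": True,
            }
        )
    if spec.noise_sd > 0:
        img = (img + rng.normal(0, spec.noise_sd, img.shape)).clip(min=0)
    truth = GroundTruth(spheres=pd.DataFrame(records))
    return img, truth


# role -> forced high_fraction for full-effect controls; None = inherit base
_ROLE_FRACTION = {"deab": 0.0, "sirna_control": 0.0}


def gen_plate_dataset(
    spec: PlateSpec,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Generate per-well cell tables plus platemap for a 384-well layout.

    Every non-empty well draws from the base mixture with role defaults
    (inhibitor-control roles force high_fraction to 0) and per-well
    overrides applied; toxicity multipliers shrink the cell count to
    ``round(mult * n_cells)``. Wells use independent substreams of the
    plate seed, keyed by row-major well index.
    """
    all_wells = well_names_384()
    tables: dict[str, pd.DataFrame] = {}
    per_well_fraction: dict[str, float] = {}
    per_well_labels: dict[str, np.ndarray] = {}
    platemap_rows = []
    for well, role in sorted(spec.layout.items()):
        compound, dose = spec.compounds.get(well, ("", 0.0))
        platemap_rows.append({"well": well, "role": role, "compound": compound,
                              "dose_uM": dose})
        if role == "empty":
            continue
        params = spec.base_mixture.model_dump()
        if role in _ROLE_FRACTION:
            params["high_fraction"] = _ROLE_FRACTION[role]
        params.update(spec.overrides.get(well, {}))
        mult = spec.toxicity.get(well, 1.0)
        params["n_cells"] = int(round(mult * params["n_cells"]))
        well_index = all_wells.index(well)
        params["seed"] = 0  # replaced below: per-well substream of plate seed
        well_spec = MixtureSpec(**params)
        rng_seed = np.random.SeedSequence((spec.seed, well_index))
        df, truth = _gen_table_with_seedseq(well_spec, rng_seed, well)
        tables[well] = df
        per_well_fraction[well] = truth.true_high_fraction
        per_well_labels[well] = truth.labels
    platemap = pd.DataFrame(platemap_rows, columns=PLATEMAP_COLUMNS)
    truth = GroundTruth(
        per_well_fraction=per_well_fraction, per_well_labels=per_well_labels
    )
    return tables, platemap, truth


def _gen_table_with_seedseq(
    spec: MixtureSpec, seedseq: np.random.SeedSequence, well: str
) -> tuple[pd.DataFrame, GroundTruth]:
    rng = np.random.default_rng(seedseq)
    n = spec.n_cells
    labels = np.where(rng.random(n) < spec.high_fraction, "high", "low")
    intensity = np.empty(n)
    low = labels == "low"
    intensity[low] = _truncated_normal(rng, spec.bg_mean, spec.bg_sd, int(low.sum()))
    intensity[~low] = _truncated_normal(
        rng, spec.high_mean, spec.high_sd_value, int((~low).sum())
    )
    xy = rng.uniform(0, 2048, size=(n, 2))
    df = pd.DataFrame(
        {
            "well": well,
            "cell_id": np.arange(n),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "nuc_area_px": np.full(n, 268.0),
            "intensity": intensity,
            "label": labels,
        },
        columns=CELL_TABLE_COLUMNS,
    )
    truth = GroundTruth(
        labels=labels,
        true_high_fraction=float((labels == "high").mean()) if n else 0.0,
        intensities=intensity,
    )
    return df, truth


@dataclass
class FourPLParams:
    top: float = 100.0
    bottom: float = 0.0
    ic50: float = 1.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")
        if self.bottom > self.top:
            raise ValueError("bottom must be <= top")


def gen_dose_response(
    params: FourPLParams,
    doses: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample a noisy 4PL dose-response curve.

    y_i = bottom + (top - bottom) / (1 + (x_i / ic50)^hill) + Normal(0, noise_sd).
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    y = four_pl(doses, params.top, params.bottom, params.ic50, params.hill)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, size=doses.shape)
    df = pd.DataFrame({"dose_uM": doses, "effect": y})
    truth = GroundTruth(four_pl=vars(params).copy())
    return df, truth
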