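"""Segmentation and image-based trait extraction.

Traits extracted from the three imaging modalities:

* six side-view RGB frames (60 degree rotation steps) -> per-view projected
  area (SA component), digital biomass DB (mean of the six areas), convex
  hull area CH, solidity SOL = DB / CH and pixel height;
* a top-view three-band reflectance stack -> top area TA and the four
  RGB vegetation indices NDVI (green-red normalized difference as used in
  this workflow, conventionally NGRDI), NPCI, PSRI and GLI;
* a dark-adapted chlorophyll-fluorescence pair (F0, Fm) -> PSII maximum
  photochemical efficiency PhE = Fv/Fm = (Fm - F0) / Fm.

All extractors are deterministic: re-running on the same rasters gives
bit-identical results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage.morphology import remove_small_objects

logger = logging.getLogger(__name__)

SIDE_VIEW_ANGLES = (0, 60, 120, 180, 240, 300)

IndexName = Literal["NDVI", "NPCI", "PSRI", "GLI"]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PlantMask:
    """Boolean raster marking plant pixels; an empty mask is valid."""

    grid: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {grid.shape}")
        object.__setattr__(self, "grid", grid)

    @property
    def pixel_count(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class SideViewSet:
    """The six segmented side views of one plant, one per rotation angle."""

    masks: tuple[PlantMask, ...]
    angles: tuple[int, ...] = SIDE_VIEW_ANGLES
    plant_id: str = ""

    def __post_init__(self):
        if len(self.masks) != 6:
            raise ValueError(f"a side-view set has exactly 6 masks, got {len(self.masks)}")
        if tuple(self.angles) != SIDE_VIEW_ANGLES:
            raise ValueError(f"side-view angles are fixed at {SIDE_VIEW_ANGLES}")
        object.__setattr__(self, "masks", tuple(self.masks))
        object.__setattr__(self, "angles", tuple(self.angles))


@dataclass(frozen=True)
class ReflectanceStack:
    """Co-registered red/green/blue reflectance rasters plus the plant mask."""

    r_red: np.ndarray
    r_green: np.ndarray
    r_blue: np.ndarray
    mask: PlantMask

    def __post_init__(self):
        shapes = {self.r_red.shape, self.r_green.shape, self.r_blue.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"reflectance bands and mask must share a shape, got {shapes}")
        if min(self.r_red.min(initial=0), self.r_green.min(initial=0),
               self.r_blue.min(initial=0)) < 0:
            raise ValueError("reflectance values must be >= 0")


@dataclass(frozen=True)
class FluorescencePair:
    """Dark-adapted minimum (F0) and maximum (Fm) fluorescence rasters."""

    f0: np.ndarray
    fm: np.ndarray
    mask: PlantMask

    def __post_init__(self):
        if not (self.f0.shape == self.fm.shape == self.mask.shape):
            raise ValueError("F0, Fm and mask must share a shape")


@dataclass
class ImageTraitRecord:
    """Per-plant image-derived trait values (areas in px^2, height in px)."""

    plant_id: str = ""
    SA: float = np.nan
    DB: float = np.nan
    CH: float = np.nan
    SOL: float = np.nan
    height_px: float = np.nan
    TA: float = np.nan
    NDVI: float = np.nan
    NPCI: float = np.nan
    PSRI: float = np.nan
    GLI: float = np.nan
    PhE: float = np.nan


# ---------------------------------------------------------------------------
# segmentation


@dataclass(frozen=True)
class SegmentationPolicy:
    """Parameters of the deterministic chroma-rule segmentation.

    Side views are shot against a saturated blue background: a pixel is
    plant iff its blue excess ``B - max(R, G)`` falls below ``blue_margin``
    (reflectances on a 0-1 scale). Top views use the excess-green rule
    ``2G - R - B > excess_green_threshold``. Connected components smaller
    than ``min_component_px`` are removed to suppress salt noise.
    """

    view: Literal["side", "top"] = "side"
    blue_margin: float = 0.2
    excess_green_threshold: float = 0.1
    min_component_px: int = 10


def _as_float_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) raster, got shape {rgb.shape}")
    if rgb.dtype == np.uint8:
        return rgb.astype(np.float64) / 255.0
    if rgb.dtype == np.uint16:
        return rgb.astype(np.float64) / 65535.0
    return rgb.astype(np.float64)


def segment_plant(rgb: np.ndarray, policy: SegmentationPolicy | None = None) -> PlantMask:
    """Segment plant pixels from a 3-channel raster.

    Returns an empty mask (not an error) for an all-background frame.
    """
    policy = policy or SegmentationPolicy()
    img = _as_float_rgb(rgb)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    if policy.view == "side":
        fg = (b - np.maximum(r, g)) < policy.blue_margin
    else:
        fg = (2.0 * g - r - b) > policy.excess_green_threshold
    if policy.min_component_px > 1 and fg.any():
        # drop 8-connected components strictly smaller than min_component_px
        fg = remove_small_objects(fg, max_size=policy.min_component_px - 1, connectivity=2)
    return PlantMask(fg)


# ---------------------------------------------------------------------------
# geometric traits


def projected_area(mask: PlantMask) -> int:
    """Projected plant area: the count of plant pixels (px^2)."""
    return mask.pixel_count


def top_area(mask: PlantMask) -> int:
    """Top-view projected area TA; identical in definition to projected_area."""
    return projected_area(mask)


def digital_biomass(areas: Sequence[float]) -> float:
    """Digital biomass DB: the arithmetic mean of the six side-view areas."""
    if len(areas) != 6:
        raise ValueError(f"digital biomass averages exactly 6 side-view areas, got {len(areas)}")
    return float(np.mean(areas))


def plant_height_px(mask: PlantMask) -> int:
    """Pixel height: raster rows spanned by plant pixels, inclusive; 0 if empty."""
    rows = np.flatnonzero(mask.grid.any(axis=1))
    if rows.size == 0:
        return 0
    return int(rows[-1] - rows[0] + 1)


def _monotone_chain(points: np.ndarray) -> np.ndarray:
    """Convex hull of 2-D points (Andrew's monotone chain), CCW order."""
    pts = np.unique(points, axis=0)  # sorts lexicographically
    if len(pts) <= 2:
        return pts

    def half(iterable):
        chain: list[np.ndarray] = []
        for p in iterable:
            while len(chain) >= 2:
                o, a = chain[-2], chain[-1]
                cross = (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0])
                if cross <= 0:
                    chain.pop()
                else:
                    break
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    return np.array(lower[:-1] + upper[:-1])


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def convex_hull_area(mask: PlantMask) -> float:
    """Area of the 2-D convex hull of plant-pixel centers (px^2).

    Uses the pixel-center convention: each plant pixel contributes the point
    (row, col). Masks with fewer than 3 non-collinear pixels have hull area 0.
    """
    coords = np.argwhere(mask.grid).astype(np.float64)
    if len(coords) < 3:
        return 0.0
    hull = _monotone_chain(coords)
    if len(hull) < 3:
        return 0.0
    return _shoelace(hull)


def solidity(db: float, ch: float) -> float:
    """Solidity SOL = digital biomass / convex hull area, in (0, 1] for real plants.

    Returns NaN (with a warning) when the hull area is zero.
    """
    if ch < 0:
        raise ValueError("convex hull area must be >= 0")
    if ch == 0:
        warnings.warn("solidity undefined: convex hull area is 0", stacklevel=2)
        return float("nan")
    return float(db) / float(ch)


# ---------------------------------------------------------------------------
# spectral and fluorescence traits

_INDEX_FORMULAS = {
    "NDVI": lambda r, g, b: ((g - r), (g + r)),
    "NPCI": lambda r, g, b: ((r - b), (r + b)),
    "PSRI": lambda r, g, b: ((r - b), g),
    "GLI": lambda r, g, b: ((2.0 * g - r - b), (2.0 * g + r + b)),
}


def spectral_index(stack: ReflectanceStack, which: IndexName) -> tuple[np.ndarray, float]:
    """Per-pixel vegetation index map and its mean over valid plant pixels.

    Formulas (reflectances R, G, B): NDVI = (G-R)/(G+R); NPCI = (R-B)/(R+B);
    PSRI = (R-B)/G; GLI = (2G-R-B)/(2G+R+B). Pixels with a zero denominator
    are excluded from the mean and counted in the log; they are NaN in the
    returned map. Returns NaN for the mean if no plant pixel is valid.
    """
    if which not in _INDEX_FORMULAS:
        raise ValueError(f"unknown index {which!r}; expected one of {sorted(_INDEX_FORMULAS)}")
    r = np.asarray(stack.r_red, dtype=np.float64)
    g = np.asarray(stack.r_green, dtype=np.float64)
    b = np.asarray(stack.r_blue, dtype=np.float64)
    num, den = _INDEX_FORMULAS[which](r, g, b)
    valid = den != 0
    index_map = np.full(r.shape, np.nan)
    np.divide(num, den, out=index_map, where=valid)

    plant = stack.mask.grid
    usable = plant & valid
    n_excluded = int(plant.sum() - usable.sum())
    if n_excluded:
        logger.info("%s: excluded %d plant pixels with zero denominator", which, n_excluded)
    mean = float(index_map[usable].mean()) if usable.any() else float("nan")
    return index_map, mean


def fvfm(pair: FluorescencePair) -> tuple[np.ndarray, float]:
    """Per-pixel Fv/Fm = (Fm - F0)/Fm and its mean over valid plant pixels.

    Pixels with Fm <= 0 or F0 outside [0, Fm] are flagged invalid, excluded
    from the mean and counted; NaN mean if every plant pixel is invalid.
    """
    f0 = np.asarray(pair.f0, dtype=np.float64)
    fm = np.asarray(pair.fm, dtype=np.float64)
    valid = (fm > 0) & (f0 >= 0) & (f0 <= fm)
    phe_map = np.full(f0.shape, np.nan)
    np.divide(fm - f0, fm, out=phe_map, where=valid)

    plant = pair.mask.grid
    usable = plant & valid
    n_excluded = int(plant.sum() - usable.sum())
    if n_excluded:
        logger.info("Fv/Fm: excluded %d invalid plant pixels", n_excluded)
    mean = float(phe_map[usable].mean()) if usable.any() else float("nan")
    return phe_map, mean


# ---------------------------------------------------------------------------
# per-plant aggregation


def side_view_traits(views: SideViewSet) -> dict[str, float]:
    """DB, CH, SOL, per-view areas, SA and height from the six side views.

    DB is the mean of the six projected areas; CH is the mean of the six
    per-view hull areas; SOL = DB / CH; SA is the summed side area over the
    six views; height is the maximum pixel height over views.
    """
    areas = [projected_area(m) for m in views.masks]
    hulls = [convex_hull_area(m) for m in views.masks]
    heights = [plant_height_px(m) for m in views.masks]
    db = digital_biomass(areas)
    ch = float(np.mean(hulls))
    return {
        "areas": areas,
        "hull_areas": hulls,
        "DB": db,
        "CH": ch,
        "SOL": solidity(db, ch) if ch > 0 else float("nan"),
        "SA": float(np.sum(areas)),
        "height_px": float(max(heights)),
    }


def extract_record(
    plant_id: str,
    views: SideViewSet | None = None,
    stack: ReflectanceStack | None = None,
    pair: FluorescencePair | None = None,
) -> ImageTraitRecord:
    """Assemble an ImageTraitRecord from whichever modalities are present.

    Missing modalities leave their traits NaN (partial-modality contract).
    """
    rec = ImageTraitRecord(plant_id=plant_id)
    if views is not None:
        sv = side_view_traits(views)
        rec.SA, rec.DB, rec.CH = sv["SA"], sv["DB"], sv["CH"]
        rec.SOL, rec.height_px = sv["SOL"], sv["height_px"]
    if stack is not None:
        rec.TA = float(top_area(stack.mask))
        for name in ("NDVI", "NPCI", "PSRI", "GLI"):
            _, mean = spectral_index(stack, name)  # type: ignore[arg-type]
            setattr(rec, name, mean)
    if pair is not None:
        _, rec.PhE = fvfm(pair)
    return rec
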