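"""Image phantoms with known ground truth.

Plants are rendered as a 3-D stick model -- a vertical stem plus tilted
branches ending in circular leaves -- projected onto the image plane at the
six turn-table azimuths (0, 60, ..., 300 degrees). The geometry is simple
on purpose: only the measurement pipeline matters, and the branch azimuths
make the projected area vary with the viewing angle, which exercises the
six-angle averaging behind digital biomass.

Ground truth is computed from the rendered foreground pixels themselves
(area = pixel count, height = row extent, hull area from pixel-center
coordinates via an independent implementation, ``scipy.spatial.ConvexHull``),
so extraction round-trips are exact by construction for area and height and
checkable against two independent hull implementations.

The phantom background is saturated blue, matching an imaging cabinet with
a blue backdrop; the generator enforces a minimum blue-channel margin
between background and plant so segmentation is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import disk, line

from peapheno.image_traits import (
    SIDE_VIEW_ANGLES,
    FluorescencePair,
    PlantMask,
    ReflectanceStack,
    SideViewSet,
)

DEFAULT_BACKGROUND = (0, 0, 255)
DEFAULT_PLANT = (20, 160, 40)

#: elevation of branches above horizontal, radians
_BRANCH_ELEVATION = np.deg2rad(30.0)


@dataclass(frozen=True)
class PlantPhantomSpec:
    """Geometry and appearance of one phantom plant.

    Lengths are in pixels; ``azimuths`` are the horizontal directions of the
    branches in degrees. ``canopy_spread`` caps the horizontal reach of any
    branch and sizes the canvas. Identical spec + seed render bit-identical
    images.
    """

    stem_height: int
    n_branches: int = 0
    branch_lengths: tuple[float, ...] = ()
    leaf_radii: tuple[float, ...] = ()
    azimuths: tuple[float, ...] = ()
    canopy_spread: int = 40
    background_color: tuple[int, int, int] = DEFAULT_BACKGROUND
    plant_color: tuple[int, int, int] = DEFAULT_PLANT
    min_channel_margin: int = 80
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.stem_height <= 0:
            raise ValueError("degenerate phantom: stem_height must be > 0")
        for name in ("branch_lengths", "leaf_radii", "azimuths"):
            vals = getattr(self, name)
            if len(vals) != self.n_branches:
                raise ValueError(f"{name} must have n_branches={self.n_branches} entries")
            object.__setattr__(self, name, tuple(float(v) for v in vals))
        if any(r <= 0 for r in self.leaf_radii):
            raise ValueError("all leaf radii must be > 0")
        if any(l <= 0 for l in self.branch_lengths):
            raise ValueError("all branch lengths must be > 0")
        bg, fg = self.background_color, self.plant_color
        if max(abs(b - f) for b, f in zip(bg, fg)) < self.min_channel_margin:
            raise ValueError(
                "background and plant colors are not separable: no channel "
                f"differs by at least {self.min_channel_margin}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Exact trait values of a rendered phantom, computed at render time."""

    true_area_per_angle: tuple[int, ...] = ()
    true_height: int = 0
    true_hull_area: tuple[float, ...] = ()
    true_top_area: int = 0
    true_index_values: dict = field(default_factory=dict)
    true_fvfm: float = float("nan")

    def __post_init__(self):
        for hull, area in zip(self.true_hull_area, self.true_area_per_angle):
            # pixel-center hull of an n-pixel blob can be smaller than n but
            # never exceeds what the blob could cover; checked loosely here
            if hull < 0 or area < 0:
                raise ValueError("areas must be non-negative")
        if self.true_index_values:
            for k, v in self.true_index_values.items():
                if k != "PSRI" and not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
                    raise ValueError(f"{k} must lie in [-1, 1], got {v}")
        if not np.isnan(self.true_fvfm) and not 0.0 <= self.true_fvfm <= 1.0:
            raise ValueError("true_fvfm must lie in [0, 1]")


def _scipy_hull_area(mask: np.ndarray) -> float:
    """Hull area of pixel centers via scipy (independent of the extractor)."""
    coords = np.argwhere(mask).astype(float)
    if len(coords) < 3:
        return 0.0
    try:
        return float(ConvexHull(coords).volume)  # 2-D: volume is the area
    except QhullError:  # collinear pixels
        return 0.0


def _render_mask(spec: PlantPhantomSpec, view_angle_deg: float, shape: tuple[int, int]) -> np.ndarray:
    """Boolean foreground mask of the phantom at one turn-table azimuth."""
    h, w = shape
    canvas = np.zeros(shape, dtype=bool)
    base_row, cx = h - 3, w // 2
    top_row = base_row - spec.stem_height + 1
    canvas[top_row:base_row + 1, cx] = True  # 1-px-wide stem

    if spec.n_branches:
        # branches attach evenly along the upper two thirds of the stem
        attach = np.linspace(0.35, 0.95, spec.n_branches) * spec.stem_height
        for frac_h, length, radius, az in zip(
            attach, spec.branch_lengths, spec.leaf_radii, spec.azimuths
        ):
            length = min(length, float(spec.canopy_spread))
            r0 = base_row - int(round(frac_h))
            dx = length * np.cos(_BRANCH_ELEVATION) * np.cos(np.deg2rad(az - view_angle_deg))
            dy = length * np.sin(_BRANCH_ELEVATION)
            r1 = int(np.clip(round(r0 - dy), 0, h - 1))
            c1 = int(np.clip(round(cx + dx), 0, w - 1))
            rr, cc = line(r0, cx, r1, c1)
            canvas[rr, cc] = True
            rr, cc = disk((r1, c1), radius, shape=shape)
            canvas[rr, cc] = True
    return canvas


def _canvas_shape(spec: PlantPhantomSpec) -> tuple[int, int]:
    max_r = int(max(spec.leaf_radii, default=0)) + 1
    height = spec.stem_height + 2 * max_r + 8
    width = 2 * (spec.canopy_spread + max_r) + 9
    return height, width


def render_side_views(spec: PlantPhantomSpec) -> tuple[SideViewSet, GroundTruth, list[np.ndarray]]:
    """Render the six side views of a phantom.

    Returns the set of true foreground masks, the ground truth derived from
    those masks, and the six RGB uint8 frames (plant on blue background,
    optionally with additive Gaussian sensor noise).
    """
    shape = _canvas_shape(spec)
    rng = np.random.default_rng(spec.seed)
    masks, images, areas, hulls, heights = [], [], [], [], []
    for angle in SIDE_VIEW_ANGLES:
        fg = _render_mask(spec, angle, shape)
        masks.append(PlantMask(fg))
        areas.append(int(fg.sum()))
        hulls.append(_scipy_hull_area(fg))
        rows = np.flatnonzero(fg.any(axis=1))
        heights.append(int(rows[-1] - rows[0] + 1) if rows.size else 0)

        img = np.empty(shape + (3,), dtype=np.float64)
        img[...] = np.asarray(spec.background_color, dtype=np.float64)
        img[fg] = np.asarray(spec.plant_color, dtype=np.float64)
        if spec.noise_sigma > 0:
            img += rng.normal(0.0, spec.noise_sigma * 255.0, size=img.shape)
        images.append(np.clip(np.round(img), 0, 255).astype(np.uint8))

    gt = GroundTruth(
        true_area_per_angle=tuple(areas),
        true_height=max(heights),
        true_hull_area=tuple(hulls),
    )
    return SideViewSet(masks=tuple(masks), plant_id=""), gt, images


# ---------------------------------------------------------------------------
# reflectance phantom


def solve_reflectance(targets: dict[str, float]) -> tuple[float, float, float]:
    """Find reflectances (R, G, B) in (0, 1] realizing the four index targets.

    The four indices have two degrees of freedom (the channel ratios R/G and
    B/R), so NDVI and NPCI fix the ratios and PSRI/GLI must be consistent
    with them. Raises ValueError naming the violated constraint otherwise.
    """
    ndvi = float(targets.get("NDVI", 0.0))
    npci = float(targets.get("NPCI", 0.0))
    if not -1.0 < ndvi < 1.0:
        raise ValueError("infeasible targets: NDVI must lie in (-1, 1) for positive R, G")
    if not -1.0 < npci < 1.0:
        raise ValueError("infeasible targets: NPCI must lie in (-1, 1) for positive R, B")

    g = 1.0
    r = g * (1.0 - ndvi) / (1.0 + ndvi)
    b = r * (1.0 - npci) / (1.0 + npci)
    scale = 0.8 / max(r, g, b)
    r, g, b = r * scale, g * scale, b * scale

    psri = (r - b) / g
    gli = (2.0 * g - r - b) / (2.0 * g + r + b)
    if "PSRI" in targets and abs(psri - targets["PSRI"]) > 1e-9:
        raise ValueError(
            f"infeasible targets: PSRI implied by NDVI/NPCI is {psri:.6g}, "
            f"requested {targets['PSRI']:.6g}"
        )
    if "GLI" in targets and abs(gli - targets["GLI"]) > 1e-9:
        raise ValueError(
            f"infeasible targets: GLI implied by NDVI/NPCI is {gli:.6g}, "
            f"requested {targets['GLI']:.6g}"
        )
    return r, g, b


def _disk_mask(shape: tuple[int, int], mask_fraction: float) -> np.ndarray:
    """Centered disk covering approximately mask_fraction of the raster."""
    h, w = shape
    radius = np.sqrt(mask_fraction * h * w / np.pi)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = disk((h / 2.0 - 0.5, w / 2.0 - 0.5), radius, shape=shape)
    mask[rr, cc] = True
    return mask


def render_reflectance_stack(
    target_indices: dict[str, float],
    shape: tuple[int, int] = (64, 64),
    mask_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[ReflectanceStack, PlantMask, GroundTruth]:
    """Render a top-view reflectance stack whose plant pixels hit the targets.

    Plant pixels carry the constant (R, G, B) reflectance solving the target
    indices; background pixels carry a blue-dominant signature distinct from
    the plant. The returned ground truth holds the realized index values and
    the plant-pixel count (true top area).
    """
    r, g, b = solve_reflectance(target_indices)
    fg = _disk_mask(shape, mask_fraction)
    bands = []
    for plant_val, bg_val in ((r, 0.05), (g, 0.05), (b, 0.9)):
        band = np.full(shape, bg_val, dtype=np.float64)
        band[fg] = plant_val
        bands.append(band)
    mask = PlantMask(fg)
    stack = ReflectanceStack(r_red=bands[0], r_green=bands[1], r_blue=bands[2], mask=mask)
    realized = {
        "NDVI": (g - r) / (g + r),
        "NPCI": (r - b) / (r + b),
        "PSRI": (r - b) / g,
        "GLI": (2 * g - r - b) / (2 * g + r + b),
    }
    gt = GroundTruth(true_top_area=int(fg.sum()), true_index_values=realized)
    return stack, mask, gt


def render_fluorescence_pair(
    target_fvfm: float,
    shape: tuple[int, int] = (64, 64),
    mask_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[FluorescencePair, PlantMask]:
    """Render a dark-adapted (F0, Fm) pair with exact per-pixel Fv/Fm.

    Plant-pixel Fm varies (seeded, in [0.5, 1.0]) while F0 = (1 - target) Fm,
    so (Fm - F0)/Fm equals the target exactly at every plant pixel.
    """
    if not 0.0 <= target_fvfm < 1.0:
        raise ValueError(f"target Fv/Fm must lie in [0, 1), got {target_fvfm}")
    rng = np.random.default_rng(seed)
    fg = _disk_mask(shape, mask_fraction)
    fm = np.zeros(shape, dtype=np.float64)
    fm[fg] = rng.uniform(0.5, 1.0, size=int(fg.sum()))
    f0 = fm * (1.0 - target_fvfm)
    return FluorescencePair(f0=f0, fm=fm, mask=PlantMask(fg)), PlantMask(fg)


def random_phantom_spec(rng: np.random.Generator, seed: int = 0) -> PlantPhantomSpec:
    """Draw a modest random phantom for round-trip testing."""
    n_branches = int(rng.integers(0, 6))
    return PlantPhantomSpec(
        stem_height=int(rng.integers(40, 120)),
        n_branches=n_branches,
        branch_lengths=tuple(rng.uniform(8, 30, n_branches)),
        leaf_radii=tuple(rng.uniform(2, 6, n_branches)),
        azimuths=tuple(rng.uniform(0, 360, n_branches)),
        canopy_spread=40,
        seed=seed,
    )
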