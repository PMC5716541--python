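"""GREIT-style figures of merit on a 32x32 pixel grid.

Reconstructions (element or node images) are resampled onto a 32x32 grid
spanning the domain's bounding square; the reconstructed object is the
quarter-amplitude set (pixels at >= 25% of the maximum absolute value,
sign-agnostic so conductive and resistive targets behave alike).  From the
thresholded masks three errors are computed per target:

* **PE** (position error, %): centroid offset between reconstructed and
  true object, as a fraction of the tank diameter (max 100%);
* **RES** (resolution, fraction) and **|dRES|** (%): ``sqrt(mask area /
  domain area)`` — a radius-ratio "size" measure — and the absolute
  difference between reconstruction and truth;
* **SD** (shape deformation, %): fraction of the reconstructed object
  lying outside the true target region.

Two-target images are split by the perpendicular bisector of the true
centers so each target is scored separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from matplotlib.tri import LinearTriInterpolator, Triangulation

from eitpost.mesh import Mesh2D

__all__ = [
    "PixelImage32",
    "TargetMask",
    "MetricsReport",
    "pixelize",
    "pixel_centers",
    "inside_mask",
    "rasterize_polygon_mask",
    "quarter_threshold",
    "split_targets",
    "position_error",
    "resolution",
    "delta_res",
    "shape_deformation",
    "score_image",
    "aggregate_study",
]

GRID = 32


@dataclass
class PixelImage32:
    """32x32 resampling of an image over the domain bounding square."""

    grid: np.ndarray  # (32, 32), NaN outside the domain
    inside: np.ndarray  # (32, 32) bool, pixel centers inside the domain

    @property
    def inside_count(self) -> int:
        return int(self.inside.sum())


@dataclass
class TargetMask:
    """Boolean pixel mask of one (reconstructed or true) object."""

    pixels: np.ndarray  # (32, 32) bool

    @property
    def area_pixels(self) -> int:
        return int(self.pixels.sum())

    @property
    def empty(self) -> bool:
        return not self.pixels.any()

    def centroid(self) -> np.ndarray:
        """Pixel-area-weighted center of gravity in domain coordinates."""
        if self.empty:
            raise ValueError("centroid of an empty mask is undefined")
        xs, ys = pixel_centers()
        sel = self.pixels
        return np.array([xs[sel].mean(), ys[sel].mean()])


@dataclass
class MetricsReport:
    """Per-target errors for one reconstructed image."""

    pe_percent: float
    res: float
    delta_res_percent: float
    sd_percent: float
    status: str = "ok"  # "ok" | "no-target"


def pixel_centers(diameter: float = 1.0):
    """(32, 32) arrays of pixel-center x and y coordinates."""
    half = diameter / 2.0
    c = -half + (np.arange(GRID) + 0.5) * (diameter / GRID)
    xs, ys = np.meshgrid(c, c, indexing="xy")
    return xs, ys


def inside_mask(diameter: float = 1.0) -> np.ndarray:
    xs, ys = pixel_centers(diameter)
    return xs**2 + ys**2 <= (diameter / 2.0) ** 2 + 1e-12


def pixelize(image: np.ndarray, mesh: Mesh2D) -> PixelImage32:
    """Resample an element or node image onto the 32x32 grid.

    Element images are point-sampled (pixel takes the value of the element
    containing its center); node images are linearly interpolated within
    the containing element.  Pixels outside the mesh carry NaN.
    """
    image = np.asarray(image, dtype=float)
    tri = _triangulation(mesh)
    xs, ys = pixel_centers(mesh.diameter)
    finder = tri.get_trifinder()
    el = finder(xs.ravel(), ys.ravel()).reshape(xs.shape)
    ins = el >= 0
    grid = np.full(xs.shape, np.nan)
    if image.shape[0] == mesh.n_elements:
        grid[ins] = image[el[ins]]
    elif image.shape[0] == mesh.n_nodes:
        interp = LinearTriInterpolator(tri, image)
        vals = interp(xs, ys)
        grid[ins] = np.asarray(vals)[ins]
    else:
        raise ValueError("image length matches neither elements nor nodes")
    return PixelImage32(grid=grid, inside=ins)


def _triangulation(mesh: Mesh2D) -> Triangulation:
    if "mpl_tri" not in mesh._cache:
        mesh._cache["mpl_tri"] = Triangulation(
            mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.elements
        )
    return mesh._cache["mpl_tri"]


def rasterize_polygon_mask(polygon, diameter: float = 1.0) -> TargetMask:
    """True-target mask: pixels whose centers fall inside a scene polygon."""
    from shapely import contains_xy

    xs, ys = pixel_centers(diameter)
    return TargetMask(contains_xy(polygon, xs, ys) & inside_mask(diameter))


def quarter_threshold(px: PixelImage32) -> TargetMask:
    """Quarter-amplitude set: ``|value| >= 0.25 * max |value|``.

    An all-zero (or all-NaN) image yields an empty mask rather than an
    exception; callers see it as ``mask.empty``.
    """
    vals = np.abs(np.where(px.inside, px.grid, np.nan))
    if not np.any(np.isfinite(vals)):
        raise ValueError("pixel image has no finite values")
    vmax = np.nanmax(vals)
    if vmax == 0.0:
        return TargetMask(np.zeros_like(px.inside, dtype=bool))
    return TargetMask((vals >= 0.25 * vmax) & px.inside)


def split_targets(mask: TargetMask, true_centers) -> tuple:
    """Partition a mask by the perpendicular bisector of two true centers.

    Pixels closer to the first center form the first submask.  The two
    submasks are disjoint and cover the input mask; either may come out
    empty (flagged downstream as "no-target").
    """
    (x1, y1), (x2, y2) = true_centers
    if math.hypot(x2 - x1, y2 - y1) < 1e-12:
        raise ValueError("coincident true centers cannot split a mask")
    xs, ys = pixel_centers()
    d1 = (xs - x1) ** 2 + (ys - y1) ** 2
    d2 = (xs - x2) ** 2 + (ys - y2) ** 2
    side1 = d1 <= d2
    return TargetMask(mask.pixels & side1), TargetMask(mask.pixels & ~side1)


def position_error(recon_mask: TargetMask, true_mask: TargetMask, diameter: float = 1.0) -> float:
    """Centroid offset over the tank diameter, percent (NaN if either empty)."""
    if recon_mask.empty or true_mask.empty:
        return float("nan")
    d = np.linalg.norm(recon_mask.centroid() - true_mask.centroid())
    return 100.0 * float(d) / diameter


def resolution(mask: TargetMask, inside_area: int) -> float:
    """RES = sqrt(mask area / domain area), the radius-ratio size measure."""
    if mask.empty:
        return float("nan")
    return math.sqrt(mask.area_pixels / inside_area)


def delta_res(recon_mask: TargetMask, true_mask: TargetMask, inside_area: int) -> float:
    """|RES_recon - RES_true| in percent."""
    r1 = resolution(recon_mask, inside_area)
    r2 = resolution(true_mask, inside_area)
    return 100.0 * abs(r1 - r2)


def shape_deformation(recon_mask: TargetMask, true_mask: TargetMask) -> float:
    """Fraction of the reconstructed object outside the true region, percent."""
    if recon_mask.empty:
        return float("nan")
    outside = recon_mask.pixels & ~true_mask.pixels
    return 100.0 * int(outside.sum()) / recon_mask.area_pixels


def score_image(image: np.ndarray, mesh: Mesh2D, true_masks: list,
                true_centers: list | None = None) -> list:
    """Full metric chain for one image against one or two true targets.

    Returns one :class:`MetricsReport` per true target.  For two targets
    the reconstructed mask is split along the perpendicular bisector of
    the true centers (``true_centers`` defaults to the true masks'
    centroids).
    """
    px = pixelize(image, mesh)
    mask = quarter_threshold(px)
    inside_area = px.inside_count
    if len(true_masks) == 1:
        parts = [mask]
    else:
        if true_centers is None:
            true_centers = [m.centroid() for m in true_masks]
        parts = list(split_targets(mask, true_centers))
    reports = []
    for part, truth in zip(parts, true_masks):
        if part.empty:
            reports.append(MetricsReport(float("nan"), float("nan"), float("nan"),
                                         float("nan"), status="no-target"))
            continue
        reports.append(
            MetricsReport(
                pe_percent=position_error(part, truth, mesh.diameter),
                res=resolution(part, inside_area),
                delta_res_percent=delta_res(part, truth, inside_area),
                sd_percent=shape_deformation(part, truth),
            )
        )
    return reports


def aggregate_study(reports: list) -> dict:
    """Mean and sample standard deviation (ddof=1) of each metric.

    Undefined ("no-target") entries are excluded; their count is reported.

    Returns a dict with keys ``pe``, ``delta_res``, ``sd`` mapping to
    ``(mean, std)`` tuples, plus ``n`` and ``n_excluded``.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    ok = [r for r in reports if r.status == "ok"]
    if not ok:
        raise ValueError("all reports are undefined; nothing to aggregate")

    def ms(vals):
        vals = np.asarray(vals, dtype=float)
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    return {
        "pe": ms([r.pe_percent for r in ok]),
        "delta_res": ms([r.delta_res_percent for r in ok]),
        "sd": ms([r.sd_percent for r in ok]),
        "n": len(ok),
        "n_excluded": len(reports) - len(ok),
    }
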