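"""Random phantom scenes: one or two contrasting targets in a disc.

Training and validation worlds contain 1-2 targets of elliptical,
triangular, or rectangular shape covering 5-40% of the domain area, with
conductivities contrasting against the background.  Two regimes mirror the
physical settings the model emulates:

* ``phantom`` — saline background 0.9 S/m with near-insulating acrylic
  targets (log-uniform in [1e-3, 0.09] S/m);
* ``lungs`` — tissue resistivity uniform in [700, 2500] Ohm cm
  (conductivity 0.04-0.143 S/m) against a 0.9 S/m background.

Scenes are analytic polygons (shapely); rasterization onto a mesh assigns
the target conductivity to elements whose centroid falls inside a target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.affinity import rotate, translate
from shapely.geometry import Point, Polygon

from eitpost.mesh import Mesh2D

__all__ = [
    "TargetSpec",
    "PhantomScene",
    "CONDUCTIVITY_REGIMES",
    "sample_scene",
    "rasterize_scene",
    "scene_polygons",
]

SHAPES = ("ellipse", "triangle", "rectangle")

#: (background S/m, (target min, target max) S/m, log-uniform?)
CONDUCTIVITY_REGIMES = {
    "phantom": (0.9, (1e-3, 0.09), True),
    # 700-2500 Ohm cm resistivity -> 1/(rho * 0.01 m/cm) S/m
    "lungs": (0.9, (1.0 / (2500 * 0.01), 1.0 / (700 * 0.01)), False),
}


@dataclass
class TargetSpec:
    """One target: shape, placement, size and conductivity."""

    shape: str  # ellipse | triangle | rectangle
    center: tuple  # (x, y), inside the unit-diameter domain
    area_fraction: float  # of the domain area, in [0.05, 0.40]
    orientation: float  # radians
    conductivity: float  # S/m
    aspect: float = 1.0  # major/minor axis (ellipse/rectangle elongation)

    def polygon(self) -> Polygon:
        return _target_polygon(self)


@dataclass
class PhantomScene:
    """1-2 non-overlapping targets plus the background conductivity."""

    targets: list
    background_conductivity: float = 0.9
    rng_seed: int | None = None

    def __post_init__(self):
        if not 1 <= len(self.targets) <= 2:
            raise ValueError("a scene holds one or two targets")


_DOMAIN_AREA = math.pi * 0.25  # unit-diameter disc


def _target_polygon(t: TargetSpec) -> Polygon:
    """Analytic polygon of the target with the requested exact area."""
    area = t.area_fraction * _DOMAIN_AREA
    if t.shape == "ellipse":
        # unit circle scaled to (a, b) with a/b = aspect, pi a b = area
        b = math.sqrt(area / (math.pi * t.aspect))
        a = t.aspect * b
        n = 64
        th = np.linspace(0, 2 * math.pi, n, endpoint=False)
        pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
        # scale so the polygonal approximation has the exact area
        poly_area = 0.5 * a * b * n * math.sin(2 * math.pi / n)
        pts *= math.sqrt(area / poly_area)
        poly = Polygon(pts)
    elif t.shape == "triangle":
        # equilateral with area s^2 sqrt(3)/4
        s = math.sqrt(4 * area / math.sqrt(3))
        h = s * math.sqrt(3) / 2
        poly = Polygon([(-s / 2, -h / 3), (s / 2, -h / 3), (0, 2 * h / 3)])
    elif t.shape == "rectangle":
        w = math.sqrt(area * t.aspect)
        h = area / w
        poly = Polygon([(-w / 2, -h / 2), (w / 2, -h / 2), (w / 2, h / 2), (-w / 2, h / 2)])
    else:
        raise ValueError(f"unknown target shape {t.shape!r}")
    poly = rotate(poly, t.orientation, origin=(0, 0), use_radians=True)
    return translate(poly, xoff=t.center[0], yoff=t.center[1])


def scene_polygons(scene: PhantomScene) -> list:
    return [t.polygon() for t in scene.targets]


def sample_scene(
    rng: np.random.Generator,
    n_targets: int | None = None,
    shape_set=SHAPES,
    regime: str = "phantom",
    area_range=(0.05, 0.40),
    max_rejections: int = 1000,
) -> PhantomScene:
    """Rejection-sample a valid scene.

    Parameters
    ----------
    rng : numpy Generator
        Source of randomness; equal seeds reproduce scenes bit-exactly.
    n_targets : int, optional
        1 or 2; ``None`` picks uniformly.
    shape_set : sequence of str
        Shapes drawn uniformly.
    regime : str
        Conductivity regime key of :data:`CONDUCTIVITY_REGIMES`.
    area_range : (float, float)
        Per-target area fraction bounds.

    Raises
    ------
    RuntimeError
        After ``max_rejections`` consecutive failures (infeasible ranges).
    """
    if not shape_set:
        raise ValueError("shape_set must be non-empty")
    background, (cmin, cmax), log_uniform = CONDUCTIVITY_REGIMES[regime]
    k = int(n_targets) if n_targets is not None else int(rng.integers(1, 3))
    if not 1 <= k <= 2:
        raise ValueError("n_targets must be 1 or 2")
    domain = Point(0, 0).buffer(0.5, quad_segs=64)
    # shapes are drawn first and kept through rejection, so each shape
    # appears with frequency 1/|shape_set| regardless of how much harder
    # some shapes are to place at large sizes
    shapes = [shape_set[int(rng.integers(len(shape_set)))] for _ in range(k)]

    def draw(shape):
        area_fraction = float(rng.uniform(*area_range))
        if log_uniform:
            conductivity = float(np.exp(rng.uniform(np.log(cmin), np.log(cmax))))
        else:
            conductivity = float(rng.uniform(cmin, cmax))
        r = float(0.5 * np.sqrt(rng.uniform(0, 1)))  # uniform in the disc
        phi = float(rng.uniform(0, 2 * math.pi))
        return TargetSpec(
            shape=shape,
            center=(r * math.cos(phi), r * math.sin(phi)),
            area_fraction=area_fraction,
            orientation=float(rng.uniform(0, 2 * math.pi)),
            conductivity=conductivity,
            aspect=float(rng.uniform(1.0, 2.0)),
        )

    rejections = 0
    while True:
        # place the whole scene; if a later target cannot fit next to an
        # earlier one, the earlier placements are redrawn too
        targets: list[TargetSpec] = []
        for shape in shapes:
            placed = False
            while rejections < max_rejections:
                spec = draw(shape)
                poly = spec.polygon()
                if domain.contains(poly) and not any(
                    poly.intersects(t.polygon()) for t in targets
                ):
                    targets.append(spec)
                    placed = True
                    break
                rejections += 1
                if targets and rejections % 100 == 0:
                    break  # restart the scene placement
            if not placed:
                break
        if len(targets) == k:
            return PhantomScene(targets=targets, background_conductivity=background)
        if rejections >= max_rejections:
            raise RuntimeError(
                f"scene sampling rejected {rejections} consecutive draws; "
                "target size/placement ranges look infeasible"
            )


def rasterize_scene(scene: PhantomScene, mesh: Mesh2D) -> np.ndarray:
    """Element conductivity field of a scene on a mesh.

    An element takes a target's conductivity when its centroid lies inside
    that target's polygon, the background conductivity otherwise.  The
    result is strictly positive (forward-solver precondition); requesting a
    non-positive target conductivity is rejected.
    """
    for t in scene.targets:
        if t.conductivity <= 0:
            raise ValueError(
                "target conductivity must be > 0 for forward solves; "
                "use a small positive value (e.g. 1e-3 S/m) for insulators"
            )
    if scene.background_conductivity <= 0:
        raise ValueError("background conductivity must be > 0")
    sigma = np.full(mesh.n_elements, scene.background_conductivity)
    cents = mesh.element_centroids()
    from shapely import contains_xy  # vectorized point-in-polygon

    for t in scene.targets:
        inside = contains_xy(t.polygon(), cents[:, 0], cents[:, 1])
        sigma[inside] = t.conductivity
    return sigma
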