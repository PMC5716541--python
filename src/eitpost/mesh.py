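"""Structured 2D triangular meshes for EIT forward and inverse modeling.

The domain is a disc (or a star-shaped perturbation of one, parameterized by
Fourier descriptors) of unit diameter, centered at the origin.  Meshes are
built as concentric rings: ring ``i`` of ``R`` carries ``4*i`` uniformly
spaced nodes, giving exactly ``4*R**2`` triangles and ``1 + 2*R*(R+1)``
nodes.  With ``R = 20`` this reproduces the reference discretization of
1600 elements and 841 nodes used throughout the package.

Electrodes are short arcs of contiguous boundary nodes (gap/shunt model):
injected current is split across an arc's nodes in proportion to attached
boundary-segment length, and the electrode voltage is the matching weighted
average of nodal potentials.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Mesh2D",
    "MeshError",
    "build_circular_mesh",
    "build_boundary_from_fourier",
    "fourier_radius",
]


class MeshError(ValueError):
    """Raised when a mesh cannot be constructed (degenerate geometry)."""


@dataclass
class Mesh2D:
    """Triangulated 2D domain with boundary electrodes.

    Attributes
    ----------
    nodes : (n_nodes, 2) float array
        Node coordinates; the domain diameter is normalized to ``diameter``.
    elements : (n_elements, 3) int array
        Node-index triples, counter-clockwise (positive signed area).
    boundary_nodes : (n_boundary,) int array
        Node indices along the outer contour, ordered counter-clockwise.
    electrode_nodes : list of int arrays
        16 (or ``n_electrodes``) disjoint groups of contiguous boundary
        node indices, ordered counter-clockwise around the contour.
    diameter : float
        Bounding diameter of the domain in node-coordinate units.
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_nodes: np.ndarray
    electrode_nodes: list
    diameter: float = 1.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_nodes)

    def element_coords(self) -> np.ndarray:
        """(E, 3, 2) coordinates of element vertices."""
        return self.nodes[self.elements]

    def element_areas(self) -> np.ndarray:
        """Signed areas; positive for a valid mesh."""
        if "areas" not in self._cache:
            p = self.element_coords()
            d1 = p[:, 1] - p[:, 0]
            d2 = p[:, 2] - p[:, 0]
            self._cache["areas"] = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
        return self._cache["areas"]

    def element_centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self.element_coords().mean(axis=1)
        return self._cache["centroids"]

    def electrode_weights(self, k: int) -> np.ndarray:
        """Current/voltage weights for electrode ``k``.

        Each node of the arc is weighted by half the length of its attached
        arc segments (trapezoid rule); weights sum to 1.  A single-node arc
        degenerates to a point electrode with weight 1.
        """
        idx = self.electrode_nodes[k]
        if len(idx) == 1:
            return np.array([1.0])
        pts = self.nodes[idx]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        w = np.zeros(len(idx))
        w[:-1] += 0.5 * seg
        w[1:] += 0.5 * seg
        return w / w.sum()

    def content_hash(self) -> str:
        """Stable hash of the geometry, electrodes included."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(np.round(self.nodes, 12)).tobytes())
        h.update(np.ascontiguousarray(self.elements.astype(np.int64)).tobytes())
        h.update(np.ascontiguousarray(self.boundary_nodes.astype(np.int64)).tobytes())
        for e in self.electrode_nodes:
            h.update(np.ascontiguousarray(np.asarray(e, dtype=np.int64)).tobytes())
        return h.hexdigest()

    def validate(self) -> None:
        areas = self.element_areas()
        if not np.all(areas > 0):
            bad = int(np.argmin(areas))
            raise MeshError(f"element {bad} has non-positive area {areas[bad]:.3e}")
        flat = np.concatenate([np.asarray(e) for e in self.electrode_nodes])
        if len(set(flat.tolist())) != len(flat):
            raise MeshError("electrode node groups overlap")


def _ring_layout(n_rings: int) -> tuple[np.ndarray, list]:
    """Node angles/radii fractions for the concentric-ring layout.

    Returns unit-disc coordinates scaled later, plus per-ring index lists.
    Ring i (1-based) has 4*i nodes at angles 2*pi*j/(4*i).
    """
    ring_index = [np.array([0])]
    angles = [0.0]
    frac = [0.0]
    start = 1
    for i in range(1, n_rings + 1):
        n = 4 * i
        ring_index.append(np.arange(start, start + n))
        angles.extend((2.0 * math.pi * np.arange(n) / n).tolist())
        frac.extend([i / n_rings] * n)
        start += n
    return np.array(angles), np.array(frac), ring_index


def _annulus_triangles(inner: np.ndarray, outer: np.ndarray) -> list:
    """Triangulate the strip between two concentric node rings.

    Both rings are ordered counter-clockwise with uniformly spaced angles
    (inner has m nodes, outer n >= m).  A two-pointer sweep by angle emits
    m + n counter-clockwise triangles.
    """
    m, n = len(inner), len(outer)
    tris = []
    p = q = 0
    ang_in = lambda k: 2.0 * math.pi * k / m
    ang_out = lambda k: 2.0 * math.pi * k / n
    for _ in range(m + n):
        adv_outer = q < n and (p >= m or ang_out(q + 1) <= ang_in(p + 1) + 1e-12)
        if adv_outer:
            tris.append((inner[p % m], outer[q % n], outer[(q + 1) % n]))
            q += 1
        else:
            tris.append((inner[p % m], outer[q % n], inner[(p + 1) % m]))
            p += 1
    return tris


_TOPOLOGY_CACHE: dict = {}


def _topology(n_rings: int):
    """Memoized connectivity for the structured layout (node count grows
    quadratically; rebuilding the element table per distorted mesh would
    dominate dataset generation)."""
    if n_rings not in _TOPOLOGY_CACHE:
        angles, frac, rings = _ring_layout(n_rings)
        elements = []
        first = rings[1]
        for j in range(4):
            elements.append((0, first[j], first[(j + 1) % 4]))
        for i in range(2, n_rings + 1):
            elements.extend(_annulus_triangles(rings[i - 1], rings[i]))
        _TOPOLOGY_CACHE[n_rings] = (
            angles,
            frac,
            np.array(elements, dtype=np.int64),
            rings[n_rings],
        )
    return _TOPOLOGY_CACHE[n_rings]


def _build_structured(n_rings: int, radius_fn, n_electrodes: int) -> Mesh2D:
    angles, frac, elements, boundary = _topology(n_rings)
    r_bound = radius_fn(angles)
    nodes = np.column_stack(
        [frac * r_bound * np.cos(angles), frac * r_bound * np.sin(angles)]
    )
    electrode_nodes = _place_electrodes(nodes, boundary, n_electrodes)
    mesh = Mesh2D(
        nodes=nodes,
        elements=elements,
        boundary_nodes=np.asarray(boundary, dtype=np.int64),
        electrode_nodes=electrode_nodes,
    )
    mesh.validate()
    return mesh


def _place_electrodes(nodes, boundary, n_electrodes, width_nodes=None):
    """Equally spaced (in boundary arclength) arcs of contiguous nodes."""
    nb = len(boundary)
    if n_electrodes > nb:
        raise MeshError(f"{n_electrodes} electrodes but only {nb} boundary nodes")
    if width_nodes is None:
        width_nodes = 2 if nb >= 2 * n_electrodes else 1
    pts = nodes[boundary]
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)[:-1]])  # arclength at each node
    total = seg.sum()
    # arclength midpoint of the arc of width_nodes nodes starting at node j
    half_span = np.zeros(nb)
    for i in range(width_nodes - 1):
        half_span += np.array([seg[(j + i) % nb] for j in range(nb)])
    mid = s + 0.5 * half_span
    groups = []
    for k in range(n_electrodes):
        # arc center for electrode k; the tiny offset breaks distance ties
        # the same way at every electrode, keeping placement rotationally
        # symmetric when the node count divides evenly
        target = k * total / n_electrodes + 1e-9 * total
        d = np.abs((mid - target + total / 2) % total - total / 2)
        j0 = int(np.argmin(d))
        groups.append(np.array([boundary[(j0 + i) % nb] for i in range(width_nodes)]))
    flat = np.concatenate(groups)
    if len(set(flat.tolist())) != len(flat):
        raise MeshError("electrode arcs overlap; too few boundary nodes per electrode")
    return groups


def _pick_rings(target_elements: int, n_electrodes: int) -> int:
    """Ring count whose 4*R^2 elements best match the target.

    Prefers R making the boundary node count (4R) a multiple of the
    electrode count so electrodes are exactly equally spaced.
    """
    step = n_electrodes // math.gcd(4, n_electrodes)
    r_star = math.sqrt(target_elements / 4.0)
    candidates = set()
    for base in (math.floor(r_star / step), math.ceil(r_star / step)):
        if base >= 1:
            candidates.add(base * step)
    best = min(candidates, key=lambda r: abs(4 * r * r - target_elements), default=None)
    if best is not None and abs(4 * best * best - target_elements) <= 0.1 * target_elements:
        return best
    # fall back to any integer R within tolerance
    r = max(1, round(r_star))
    if abs(4 * r * r - target_elements) > 0.1 * target_elements:
        raise MeshError(
            f"cannot reach {target_elements} elements within 10% with the structured mesher"
        )
    return r


def build_circular_mesh(target_elements: int = 1600, n_electrodes: int = 16) -> Mesh2D:
    """Build the reference circular tank mesh.

    Parameters
    ----------
    target_elements : int
        Desired triangle count (>= 100 for production meshes; small values
        are allowed for toy problems).  The achieved count is within 10%.
    n_electrodes : int
        Number of equally spaced boundary electrodes (>= 4).

    Returns
    -------
    Mesh2D
        Unit-diameter disc mesh.  ``(1600, 16)`` yields exactly 1600
        elements and 841 nodes.
    """
    if target_elements < 4:
        raise MeshError("target_elements must be at least 4")
    if n_electrodes < 4:
        raise MeshError("need at least 4 electrodes")
    n_rings = _pick_rings(target_elements, n_electrodes)
    return _build_structured(n_rings, lambda th: np.full_like(th, 0.5), n_electrodes)


def fourier_radius(coeffs: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Radius of a Fourier-descriptor contour.

    ``coeffs`` has shape (H+1, 2); row 0 holds ``(r0, 0)`` (the mean radius)
    and row n >= 1 holds the cosine/sine amplitudes ``(a_n, b_n)`` relative
    to ``r0``:  r(theta) = r0 * (1 + sum_n a_n cos(n theta) + b_n sin(n theta)).
    """
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    r0 = coeffs[0, 0]
    r = np.ones_like(theta)
    for n in range(1, coeffs.shape[0]):
        a, b = coeffs[n]
        r = r + a * np.cos(n * theta) + b * np.sin(n * theta)
    return r0 * r


def build_boundary_from_fourier(
    coeffs: np.ndarray, target_elements: int = 1600, n_electrodes: int = 16
) -> Mesh2D:
    """Mesh a star-shaped domain whose boundary is a Fourier contour.

    The ring topology (hence node/element counts and indexing) is identical
    to :func:`build_circular_mesh` at the same ``target_elements``; only node
    positions move.  This lets a distorted forward mesh and the undistorted
    inverse mesh share element indexing.  Electrodes are equally spaced in
    boundary arclength.

    Raises
    ------
    MeshError
        If the contour radius becomes non-positive (the radial
        parameterization would self-intersect); the error names the largest
        offending harmonic.
    """
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    if coeffs[0, 0] <= 0:
        raise MeshError("mean radius r0 must be positive")
    theta = np.linspace(0.0, 2.0 * math.pi, 2048, endpoint=False)
    r = fourier_radius(coeffs, theta)
    if np.any(r <= 0):
        amps = np.hypot(coeffs[1:, 0], coeffs[1:, 1])
        worst = int(np.argmax(amps)) + 1 if len(amps) else 0
        raise MeshError(
            f"contour self-intersects (radius <= 0); largest harmonic n={worst} "
            f"amplitude {amps[worst - 1]:.3f}" if len(amps) else "contour radius <= 0"
        )
    n_rings = _pick_rings(target_elements, n_electrodes)
    return _build_structured(n_rings, lambda th: fourier_radius(coeffs, th), n_electrodes)
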