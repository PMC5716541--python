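"""Linear FEM forward solver for the 2D EIT problem and its adjoint Jacobian.

The governing equation is the quasi-static conduction equation
``div(sigma grad u) = 0`` in the domain, with Neumann boundary data set by
the injected current.  Piecewise-linear (P1) elements with piecewise-constant
conductivity reduce it to a sparse symmetric system ``K(sigma) u = b``; the
all-Neumann nullspace (additive constants) is removed with a Lagrange
multiplier enforcing a zero-mean potential per drive.

The sensitivity of channel voltages to element conductivities uses the
adjoint identity: because measurement patterns equal drive patterns under
the adjacent protocol, ``dV(d,m)/dsigma_e = -(area_e / I) * grad(u_d) .
grad(u_m)``, exact for the discrete system (``K`` is linear in ``sigma``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from eitpost.mesh import Mesh2D
from eitpost.protocol import StimulationProtocol

__all__ = [
    "MeasurementFrame",
    "ForwardSolution",
    "JacobianMatrix",
    "ForwardError",
    "solve_forward",
    "compute_jacobian",
    "frame_voltages",
]


class ForwardError(RuntimeError):
    """Raised when the forward system cannot be solved."""


@dataclass
class MeasurementFrame:
    """One stimulation sweep: 256 differential voltages.

    ``voltages`` is flat in (drive, measure) order: channel ``16*d + m``.
    """

    voltages: np.ndarray

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim != 1:
            raise ValueError("frame voltages must be a flat vector")

    def __len__(self) -> int:
        return len(self.voltages)

    def as_matrix(self) -> np.ndarray:
        n = int(round(np.sqrt(len(self.voltages))))
        return self.voltages.reshape(n, n)


def frame_voltages(frame) -> np.ndarray:
    """Accept a MeasurementFrame or a bare vector; return the flat vector."""
    if isinstance(frame, MeasurementFrame):
        return frame.voltages
    return np.asarray(frame, dtype=float)


@dataclass
class ForwardSolution:
    """Nodal potentials for every drive plus the extracted frame."""

    node_potentials: np.ndarray  # (n_nodes, n_drives), volts
    frame: MeasurementFrame


@dataclass
class JacobianMatrix:
    """Channel-by-element sensitivity matrix at a background conductivity."""

    J: np.ndarray  # (n_channels, n_elements), V per (S/m)
    sigma0: np.ndarray
    mesh_hash: str = ""


def _gradient_operators(mesh: Mesh2D):
    """Sparse (E x N) operators mapping nodal values to element gradients."""
    p = mesh.element_coords()
    areas = mesh.element_areas()
    # grad of P1 basis i on a triangle: rotate opposite edge by 90 deg / 2A
    b = np.stack(
        [
            p[:, 1, 1] - p[:, 2, 1],
            p[:, 2, 1] - p[:, 0, 1],
            p[:, 0, 1] - p[:, 1, 1],
        ],
        axis=1,
    )
    c = np.stack(
        [
            p[:, 2, 0] - p[:, 1, 0],
            p[:, 0, 0] - p[:, 2, 0],
            p[:, 1, 0] - p[:, 0, 0],
        ],
        axis=1,
    )
    inv2a = 1.0 / (2.0 * areas)
    rows = np.repeat(np.arange(mesh.n_elements), 3)
    cols = mesh.elements.ravel()
    shape = (mesh.n_elements, mesh.n_nodes)
    dx = sp.csr_matrix(((b * inv2a[:, None]).ravel(), (rows, cols)), shape=shape)
    dy = sp.csr_matrix(((c * inv2a[:, None]).ravel(), (rows, cols)), shape=shape)
    return dx, dy, areas


def _stiffness(mesh: Mesh2D, sigma: np.ndarray) -> sp.csc_matrix:
    dx, dy, areas = _grad_cache(mesh)
    w = sp.diags(sigma * areas)
    return (dx.T @ w @ dx + dy.T @ w @ dy).tocsc()


def _grad_cache(mesh: Mesh2D):
    if "grad_ops" not in mesh._cache:
        mesh._cache["grad_ops"] = _gradient_operators(mesh)
    return mesh._cache["grad_ops"]


def _electrode_vectors(mesh: Mesh2D, protocol: StimulationProtocol) -> np.ndarray:
    """(n_nodes, n_electrodes) matrix of per-electrode nodal weights."""
    if "elec_vecs" in mesh._cache:
        return mesh._cache["elec_vecs"]
    W = np.zeros((mesh.n_nodes, mesh.n_electrodes))
    for k in range(mesh.n_electrodes):
        W[mesh.electrode_nodes[k], k] = mesh.electrode_weights(k)
    mesh._cache["elec_vecs"] = W
    return W


def _pair_matrix(mesh: Mesh2D, protocol: StimulationProtocol) -> np.ndarray:
    """(n_nodes, n_pairs): +weights on the first electrode, - on the second."""
    W = _electrode_vectors(mesh, protocol)
    cols = []
    for a, b in protocol.drive_pairs:
        cols.append(W[:, a] - W[:, b])
    return np.column_stack(cols)


def solve_forward(
    mesh: Mesh2D, sigma: np.ndarray, protocol: StimulationProtocol
) -> ForwardSolution:
    """Solve the forward problem for every drive of the protocol.

    Parameters
    ----------
    mesh, protocol
        Geometry and adjacent stimulation pattern; electrode count must
        match the mesh's electrode groups.
    sigma : (n_elements,) array
        Strictly positive element conductivities, S/m.

    Returns
    -------
    ForwardSolution
        Nodal potentials (zero mean per drive) and the 256-channel frame;
        channels on driving electrodes are kept.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (mesh.n_elements,):
        raise ValueError("sigma length must equal the element count")
    if np.any(sigma <= 0) or not np.all(np.isfinite(sigma)):
        raise ForwardError("conductivity must be strictly positive and finite")
    if mesh.n_electrodes != protocol.n_electrodes:
        raise ValueError("mesh and protocol electrode counts differ")

    K = _stiffness(mesh, sigma)
    n = mesh.n_nodes
    ones = np.ones((n, 1))
    A = sp.bmat([[K, ones], [ones.T, None]], format="csc")
    P = _pair_matrix(mesh, protocol)  # drive/measure patterns coincide
    B = np.vstack([protocol.current_amplitude * P, np.zeros((1, P.shape[1]))])
    try:
        lu = spla.splu(A)
    except RuntimeError as exc:  # singular factorization
        raise ForwardError(f"singular forward system: {exc}") from exc
    U = lu.solve(B)[:n]
    if not np.all(np.isfinite(U)):
        raise ForwardError("forward solve produced non-finite potentials")
    # voltages: V[d, m] = measure-pattern m applied to drive-d potentials
    V = (P.T @ U).T  # (n_drives, n_measures)
    return ForwardSolution(node_potentials=U, frame=MeasurementFrame(V.ravel()))


def compute_jacobian(
    mesh: Mesh2D, sigma0: np.ndarray, protocol: StimulationProtocol
) -> JacobianMatrix:
    """Adjoint-method Jacobian of channel voltages w.r.t. element conductivity.

    Exploits that adjacent measurement patterns equal drive patterns, so the
    adjoint fields are the (scaled) forward fields themselves and one
    factorization yields the full 256 x n_elements matrix.
    """
    sol = solve_forward(mesh, sigma0, protocol)
    dx, dy, areas = _grad_cache(mesh)
    gx = dx @ sol.node_potentials  # (E, n_drives)
    gy = dy @ sol.node_potentials
    # J[(d,m), e] = -(area_e / I) * grad(u_d) . grad(u_m)
    amp = protocol.current_amplitude
    J = -(np.einsum("ed,em->dme", gx, gx) + np.einsum("ed,em->dme", gy, gy))
    J *= areas[None, None, :] / amp
    n_ch = protocol.n_channels
    return JacobianMatrix(
        J=J.reshape(n_ch, mesh.n_elements),
        sigma0=np.asarray(sigma0, dtype=float).copy(),
        mesh_hash=mesh.content_hash(),
    )
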