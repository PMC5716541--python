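"""Training/validation world generation for the post-processing pipeline.

Each sample follows the same flow the physical experiments imply:

1. draw a random scene (1-2 contrasting targets in the disc);
2. perturb the Fourier descriptors of the boundary and build a distorted
   forward mesh (the inverse mesh is never distorted — that mismatch is
   exactly what the post-processor must learn to tolerate);
3. solve the forward problem on the distorted mesh for the target field
   and for the homogeneous reference (time-difference baseline);
4. optionally push both frames through the raw-signal noise model;
5. reconstruct the difference frame with one-step GN on the undistorted
   mesh, and rasterize the true conductivity change on that same mesh.

Both the clean and the noisy branches are stored, so the same generated
world can train networks with or without noise and serve as a validation
set at either noise setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from eitpost.forward import solve_forward
from eitpost.inverse import GNInverseModel, gn_reconstruct
from eitpost.mesh import Mesh2D, build_boundary_from_fourier
from eitpost.noise import NoiseModel, synthesize_noisy_frame
from eitpost.protocol import StimulationProtocol
from eitpost.rbf import map_elements_to_nodes
from eitpost.scenes import PhantomScene, rasterize_scene, sample_scene

__all__ = ["BoundaryPerturbation", "TrainingDataset", "build_dataset"]


@dataclass
class BoundaryPerturbation:
    """Random Fourier-descriptor distortion of the forward-model boundary.

    Each retained harmonic (2-8 by default) receives i.i.d. Gaussian
    cosine/sine amplitudes with relative standard deviation ``sigma_rel``
    (~3% radial deviation): visible deformation without self-intersection.
    """

    sigma_rel: float = 0.03
    harmonics: tuple = (2, 3, 4, 5, 6, 7, 8)

    def sample_coeffs(self, rng: np.random.Generator, r0: float = 0.5) -> np.ndarray:
        hmax = max(self.harmonics) if self.harmonics else 0
        coeffs = np.zeros((hmax + 1, 2))
        coeffs[0, 0] = r0
        for n in self.harmonics:
            coeffs[n] = rng.normal(0.0, self.sigma_rel, size=2)
        return coeffs


def _sample_valid_distortion(distortion, rng, n_elements, n_electrodes, max_tries=50):
    """Draw distortion coefficients until the deformed mesh is valid.

    Strong high-harmonic draws can fold boundary slivers (negative areas);
    those draws are physically meaningless boundaries and are rejected,
    like out-of-domain targets in scene sampling.
    """
    from eitpost.mesh import MeshError

    last = None
    for _ in range(max_tries):
        coeffs = distortion.sample_coeffs(rng)
        try:
            mesh = build_boundary_from_fourier(
                coeffs, target_elements=n_elements, n_electrodes=n_electrodes
            )
            return coeffs, mesh
        except MeshError as exc:
            last = exc
    raise RuntimeError(f"no valid boundary distortion in {max_tries} draws: {last}")


@dataclass
class TrainingDataset:
    """Aligned per-sample arrays for network training and validation."""

    mode: str  # "postprocess" | "direct"
    noisy: bool  # whether the default inputs use the noisy branch
    dv_clean: np.ndarray  # (n, 256)
    dv_noisy: np.ndarray | None
    gn_clean: np.ndarray  # (n, n_elements) GN images of the clean frames
    gn_noisy: np.ndarray | None
    truth_elements: np.ndarray  # (n, n_elements) true conductivity change
    truth_nodes: np.ndarray  # (n, n_nodes)
    scenes: list  # PhantomScene per sample
    coeffs: list  # boundary Fourier coefficients per sample
    mesh_hash: str
    master_seed: int | None = None
    _mesh: Mesh2D | None = field(default=None, repr=False, compare=False)

    @property
    def n_samples(self) -> int:
        return self.dv_clean.shape[0]

    def inputs_for(self, mode: str, noisy: bool) -> np.ndarray:
        """Input matrix for a given network role and noise branch."""
        if noisy and self.dv_noisy is None:
            raise ValueError("dataset was generated without a noise model")
        if mode == "direct":
            return self.dv_noisy if noisy else self.dv_clean
        if mode == "postprocess":
            gn = self.gn_noisy if noisy else self.gn_clean
            return np.stack([map_elements_to_nodes(g, self._mesh) for g in gn])
        raise ValueError(f"unknown mode {mode!r}")

    @property
    def inputs(self) -> np.ndarray:
        return self.inputs_for(self.mode, self.noisy)

    @property
    def outputs(self) -> np.ndarray:
        return self.truth_nodes


def build_dataset(
    n_samples: int,
    mesh: Mesh2D,
    model: GNInverseModel,
    protocol: StimulationProtocol,
    rng: np.random.Generator,
    mode: str = "postprocess",
    distortion: BoundaryPerturbation | None = None,
    noise: NoiseModel | None = None,
    n_targets: int | None = None,
    shape_set=("ellipse", "triangle", "rectangle"),
    regime: str = "phantom",
) -> TrainingDataset:
    """Generate ``n_samples`` aligned input/output pairs.

    Parameters
    ----------
    mesh : Mesh2D
        The undistorted reconstruction mesh (reference geometry).
    model : GNInverseModel
        Precomputed one-step GN operator on ``mesh``.
    rng : numpy Generator
        Master randomness; the dataset is a pure function of (settings, rng
        state).
    mode, noise, distortion
        Network role the default ``inputs`` serve, optional raw-signal
        noise model, and optional boundary distortion (forward model only).
    n_targets : int or None
        Fix 1 or 2 targets per scene, or None for a random mix.

    Raises
    ------
    RuntimeError
        If any per-sample stage fails; the message carries the sample index
        (samples are never silently skipped).
    """
    if model.mesh_hash and model.mesh_hash != mesh.content_hash():
        raise ValueError("GN model was built for a different mesh")
    n_el, n_nodes = mesh.n_elements, mesh.n_nodes
    n_ch = protocol.n_channels
    dv_clean = np.empty((n_samples, n_ch))
    dv_noisy = np.empty((n_samples, n_ch)) if noise is not None else None
    gn_clean = np.empty((n_samples, n_el))
    gn_noisy = np.empty((n_samples, n_el)) if noise is not None else None
    truth_el = np.empty((n_samples, n_el))
    truth_nd = np.empty((n_samples, n_nodes))
    scenes: list[PhantomScene] = []
    coeffs_list: list[np.ndarray] = []

    for i in range(n_samples):
        try:
            scene = sample_scene(rng, n_targets=n_targets, shape_set=shape_set, regime=regime)
            if distortion is not None:
                coeffs, fwd_mesh = _sample_valid_distortion(
                    distortion, rng, n_el, protocol.n_electrodes
                )
            else:
                coeffs = np.array([[0.5, 0.0]])
                fwd_mesh = mesh
            # truth by element index on the reference mesh; the distortion
            # carries the same element values onto the deformed domain
            sigma_t = rasterize_scene(scene, mesh)
            sigma_ref = np.full(n_el, scene.background_conductivity)
            v_meas = solve_forward(fwd_mesh, sigma_t, protocol).frame
            v_ref = solve_forward(fwd_mesh, sigma_ref, protocol).frame
            dv = v_meas.voltages - v_ref.voltages
            dv_clean[i] = dv
            gn_clean[i] = gn_reconstruct(model, dv)
            if noise is not None:
                nm = synthesize_noisy_frame(v_meas, noise, rng).voltages
                nr = synthesize_noisy_frame(v_ref, noise, rng).voltages
                dv_noisy[i] = nm - nr
                gn_noisy[i] = gn_reconstruct(model, dv_noisy[i])
            truth_el[i] = sigma_t - sigma_ref
            truth_nd[i] = map_elements_to_nodes(truth_el[i], mesh)
            scenes.append(scene)
            coeffs_list.append(coeffs)
        except Exception as exc:
            raise RuntimeError(f"dataset sample {i} failed: {exc}") from exc

    return TrainingDataset(
        mode=mode,
        noisy=noise is not None,
        dv_clean=dv_clean,
        dv_noisy=dv_noisy,
        gn_clean=gn_clean,
        gn_noisy=gn_noisy,
        truth_elements=truth_el,
        truth_nodes=truth_nd,
        scenes=scenes,
        coeffs=coeffs_list,
        mesh_hash=mesh.content_hash(),
        _mesh=mesh,
    )
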