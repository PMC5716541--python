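# eitpost

2D electrical impedance tomography (EIT) with an RBF-network
post-processor: simulate boundary-voltage measurements on a 16-electrode
tank by finite elements, reconstruct conductivity changes with a linear
one-step Gauss–Newton solver, and sharpen the linear image with a radial
basis function network trained purely on simulated phantoms.

## Who it is for

EIT reconstructs the conductivity distribution inside a body from currents
injected and voltages read at boundary electrodes — safe, fast, and
non-invasive, but severely ill-posed: practical solvers linearize the
problem and produce heavily smoothed images.  Neural networks applied
directly to the voltages recover sharper images but break down under
measurement noise and boundary-shape mismatch, which are unavoidable in
practice (a thorax is never the model's circle, and it moves).  This
package implements — and quantifies, on fully simulated data — a hybrid:
let the robust linear solver absorb the noise and modeling error, then
train a network only to undo the linear solver's smoothing.  It is aimed
at people studying EIT reconstruction algorithms who want a
self-contained, reproducible simulation test bench.

## The pipeline

* **Forward model** (`eitpost.mesh`, `eitpost.forward`) — P1 finite
  elements on a structured disc mesh (1600 triangles / 841 nodes at the
  reference resolution) or on Fourier-descriptor-distorted domains;
  adjacent current-injection protocol, 256 channels per frame; adjoint
  Jacobian `∂V/∂σₑ = −(areaₑ/I)∇u_d·∇u_m`.
* **Inverse solvers** (`eitpost.inverse`) — one-step Gauss–Newton with
  the NOSER prior, `RM = (JᵀWJ + αP)⁻¹JᵀW`, precomputed so that
  reconstruction is a single matrix product; plus a five-iteration
  primal-dual interior-point total-variation comparator.
* **Synthetic worlds** (`eitpost.scenes`, `eitpost.noise`,
  `eitpost.dataset`) — random 1–2-target scenes (ellipse / triangle /
  rectangle, 5–40% of the domain, saline-vs-insulator or lung-tissue
  conductivities), random boundary distortion applied only to the forward
  model, and a raw-signal noise model (100 kHz carrier, channel-dependent
  SNR, tenth-order bandpass, peak detection).
* **RBF network** (`eitpost.rbf`) — Gaussian hidden layer
  (`exp(−(‖x−t‖/s)²)`, 400 units), linear output layer; usable as a
  direct inverse solver (input: voltages) or as the post-processor
  (input: the Gauss–Newton image on the 841 nodes).
* **Figures of merit** (`eitpost.metrics`) — 32×32 pixelization,
  quarter-amplitude thresholding, and position error (PE), size error
  (|ΔRES|), and shape deformation (SD), with two-target splitting.
* **Study runner** (`eitpost.study`, `eit` CLI) — the end-to-end
  experiment: generate, train, reconstruct with four methods, score,
  aggregate.

## Worked example

```python
import numpy as np
from eitpost import (build_circular_mesh, adjacent_protocol, solve_forward,
                     compute_jacobian, build_reconstruction_matrix, gn_reconstruct,
                     TargetSpec, PhantomScene, rasterize_scene)
from eitpost.metrics import rasterize_polygon_mask, score_image

mesh = build_circular_mesh(1600, 16)
protocol = adjacent_protocol()
print(f"mesh: {mesh.n_elements} elements, {mesh.n_nodes} nodes")

background = np.full(mesh.n_elements, 0.9)          # saline, S/m
scene = PhantomScene([TargetSpec("triangle", (0.12, 0.05), 0.10, 0.6, 0.005)])
sigma = rasterize_scene(scene, mesh)                # insulating triangle

ref = solve_forward(mesh, background, protocol).frame
meas = solve_forward(mesh, sigma, protocol).frame
model = build_reconstruction_matrix(compute_jacobian(mesh, background, protocol))
image = gn_reconstruct(model, meas.voltages - ref.voltages)

truth = rasterize_polygon_mask(scene.targets[0].polygon())
rep = score_image(image, mesh, [truth])[0]
print(f"GN: PE = {rep.pe_percent:.2f}%, |dRES| = {rep.delta_res_percent:.2f}%, "
      f"SD = {rep.sd_percent:.2f}%")
```

prints

```
mesh: 1600 elements, 841 nodes
GN: PE = 1.27%, |dRES| = 3.68%, SD = 33.66%
```

The time-difference Gauss–Newton image localizes a clean, undistorted
target almost perfectly (centroid off by 1.3% of the tank diameter) and
estimates its size well, but the heavy smoothing spills 34% of the
reconstructed object outside the true triangle — the deformation the
post-processor is there to remove.  Under boundary distortion and channel
noise the GN position error grows to several percent (see the study
below), while the post-processed reconstruction stays near 2–3%.

The full comparison — one-step GN, PDIPM, the network as a direct solver,
and GN + network — is one call:

```sh
eit study --seed 0 --n-train 2000 --n-validation 2000 --out rows.csv
```

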