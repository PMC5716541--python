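"""Independent analytic oracle: concentric two-layer disc.

Series solution for boundary potentials under arc-electrode drives,
used to validate the FEM forward solver.
"""

import numpy as np


def two_layer_frame(mesh, protocol, a, sigma1, sigma2, n_harmonics=400):
    """Series solution for electrode-pair drives on a two-layer disc.

    Current enters through uniform densities over each electrode arc; the
    electrode voltage is the arc average of the boundary potential.  Per
    harmonic n the radial solution is A r^n inside, B r^n + C r^-n in the
    annulus, matched at r=a and driven at r=b.
    """
    b = 0.5
    # electrode arc centers and angular widths
    centers, widths = [], []
    for k in range(mesh.n_electrodes):
        pts = mesh.nodes[mesh.electrode_nodes[k]]
        ang = np.unwrap(np.arctan2(pts[:, 1], pts[:, 0]))
        centers.append(ang.mean())
        widths.append(ang.max() - ang.min())
    centers, widths = np.array(centers), np.array(widths)
    I = protocol.current_amplitude

    def electrode_potentials(drive):
        da, db = protocol.drive_pairs[drive]
        u = np.zeros(mesh.n_electrodes)
        for n in range(1, n_harmonics + 1):
            # current-density Fourier coefficients for the +/- arc pair
            sinc_d = np.sin(n * widths / 2) / (n * widths / 2)
            jc = I / (np.pi * b) * (
                np.cos(n * centers[da]) * sinc_d[da] - np.cos(n * centers[db]) * sinc_d[db]
            )
            js = I / (np.pi * b) * (
                np.sin(n * centers[da]) * sinc_d[da] - np.sin(n * centers[db]) * sinc_d[db]
            )
            # solve the 3x3 radial matching system for (A, B, C)
            M = np.array(
                [
                    [a**n, -(a**n), -(a ** (-n))],
                    [sigma1 * n * a ** (n - 1), -sigma2 * n * a ** (n - 1), sigma2 * n * a ** (-n - 1)],
                    [0.0, sigma2 * n * b ** (n - 1), -sigma2 * n * b ** (-n - 1)],
                ]
            )
            Bc, Cc = np.linalg.solve(M, [0.0, 0.0, jc])[1:]
            Bs, Cs = np.linalg.solve(M, [0.0, 0.0, js])[1:]
            amp_c = Bc * b**n + Cc * b ** (-n)
            amp_s = Bs * b**n + Cs * b ** (-n)
            # arc-averaged boundary potential at each electrode
            sinc_m = np.sin(n * widths / 2) / (n * widths / 2)
            u += sinc_m * (amp_c * np.cos(n * centers) + amp_s * np.sin(n * centers))
        return u

    frame = np.empty(protocol.n_channels)
    for d in range(mesh.n_electrodes):
        u = electrode_potentials(d)
        for m, (ma, mb) in enumerate(protocol.measure_pairs):
            frame[16 * d + m] = u[ma] - u[mb]
    return frame
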