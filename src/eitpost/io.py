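"""Persistence: plain-text and HDF5 round-trips for the pipeline artifacts.

Meshes round-trip exactly through a plain-text bundle (node table, element
table, electrode map) or a single HDF5 file; frames through CSV
(``drive,measure,voltage`` at 17 significant digits) or HDF5; datasets and
networks through HDF5 bundles that embed the mesh hash so mismatched
combinations are refused at load time.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from eitpost.dataset import TrainingDataset
from eitpost.forward import MeasurementFrame, frame_voltages
from eitpost.inverse import GNInverseModel
from eitpost.mesh import Mesh2D
from eitpost.rbf import RBFNetwork


def _stamp(f):
    """Embed the package version in every HDF5 artifact."""
    import eitpost

    f.attrs["eitpost_version"] = eitpost.__version__

__all__ = [
    "save_mesh_text",
    "load_mesh_text",
    "save_mesh_h5",
    "load_mesh_h5",
    "save_frame_csv",
    "load_frame_csv",
    "save_frame_h5",
    "load_frame_h5",
    "save_network_h5",
    "load_network_h5",
    "save_gn_model_h5",
    "load_gn_model_h5",
    "save_dataset_h5",
    "load_dataset_h5",
]


# -- meshes -----------------------------------------------------------------

def save_mesh_text(mesh: Mesh2D, prefix) -> None:
    """Write ``<prefix>.nodes.txt``, ``<prefix>.elements.txt`` and
    ``<prefix>.electrodes.json``."""
    prefix = Path(prefix)
    with open(f"{prefix}.nodes.txt", "w") as fh:
        for i, (x, y) in enumerate(mesh.nodes):
            fh.write(f"{i}\t{float(x)!r}\t{float(y)!r}\n")
    with open(f"{prefix}.elements.txt", "w") as fh:
        for i, (a, b, c) in enumerate(mesh.elements):
            fh.write(f"{i}\t{a}\t{b}\t{c}\n")
    meta = {
        "boundary_nodes": mesh.boundary_nodes.tolist(),
        "electrode_nodes": [np.asarray(e).tolist() for e in mesh.electrode_nodes],
        "diameter": mesh.diameter,
    }
    Path(f"{prefix}.electrodes.json").write_text(json.dumps(meta))


def load_mesh_text(prefix) -> Mesh2D:
    prefix = Path(prefix)
    nodes = np.loadtxt(f"{prefix}.nodes.txt", usecols=(1, 2), ndmin=2)
    elements = np.loadtxt(f"{prefix}.elements.txt", usecols=(1, 2, 3), dtype=np.int64, ndmin=2)
    meta = json.loads(Path(f"{prefix}.electrodes.json").read_text())
    return Mesh2D(
        nodes=nodes,
        elements=elements,
        boundary_nodes=np.asarray(meta["boundary_nodes"], dtype=np.int64),
        electrode_nodes=[np.asarray(e, dtype=np.int64) for e in meta["electrode_nodes"]],
        diameter=float(meta["diameter"]),
    )


def save_mesh_h5(mesh: Mesh2D, path) -> None:
    with h5py.File(path, "w") as f:
        f["nodes"] = mesh.nodes
        f["elements"] = mesh.elements
        f["boundary_nodes"] = mesh.boundary_nodes
        for k, e in enumerate(mesh.electrode_nodes):
            f[f"electrodes/{k:03d}"] = np.asarray(e, dtype=np.int64)
        f.attrs["diameter"] = mesh.diameter
        f.attrs["content_hash"] = mesh.content_hash()
        _stamp(f)


def load_mesh_h5(path) -> Mesh2D:
    with h5py.File(path, "r") as f:
        mesh = Mesh2D(
            nodes=f["nodes"][...],
            elements=f["elements"][...],
            boundary_nodes=f["boundary_nodes"][...],
            electrode_nodes=[f[f"electrodes/{k}"][...] for k in sorted(f["electrodes"])],
            diameter=float(f.attrs["diameter"]),
        )
        stored = f.attrs.get("content_hash", "")
    if stored and stored != mesh.content_hash():
        raise ValueError(f"mesh bundle {path} is corrupt: content hash mismatch")
    return mesh


# -- frames -----------------------------------------------------------------

def save_frame_csv(frame, path, n_electrodes: int = 16) -> None:
    v = frame_voltages(frame)
    d, m = np.divmod(np.arange(len(v)), n_electrodes)
    pd.DataFrame({"drive": d, "measure": m, "voltage": v}).to_csv(
        path, index=False, float_format="%.17g"
    )


def load_frame_csv(path) -> MeasurementFrame:
    df = pd.read_csv(path)
    order = np.lexsort((df["measure"], df["drive"]))
    return MeasurementFrame(df["voltage"].to_numpy()[order])


def save_frame_h5(frame, path) -> None:
    with h5py.File(path, "w") as f:
        f["voltages"] = frame_voltages(frame)
        _stamp(f)


def load_frame_h5(path) -> MeasurementFrame:
    with h5py.File(path, "r") as f:
        return MeasurementFrame(f["voltages"][...])


# -- reconstruction operators ----------------------------------------------

def save_gn_model_h5(model: GNInverseModel, path) -> None:
    """Persist a precomputed one-step GN operator.

    The bundle keys the matrix by mesh hash and regularization settings so
    reconstruction at run time is a pure matrix product.
    """
    with h5py.File(path, "w") as f:
        f["RM"] = model.RM
        f["J"] = model.J
        f["P_diag"] = np.diag(model.P)
        if model.omega is not None:
            f["omega"] = model.omega
        f.attrs["alpha"] = model.alpha
        f.attrs["mesh_hash"] = model.mesh_hash
        _stamp(f)


def load_gn_model_h5(path, mesh: Mesh2D | None = None) -> GNInverseModel:
    with h5py.File(path, "r") as f:
        mesh_hash = str(f.attrs["mesh_hash"])
        if mesh is not None and mesh.content_hash() != mesh_hash:
            raise ValueError("GN model was built for a different mesh")
        return GNInverseModel(
            J=f["J"][...],
            omega=f["omega"][...] if "omega" in f else None,
            alpha=float(f.attrs["alpha"]),
            P=np.diag(f["P_diag"][...]),
            RM=f["RM"][...],
            mesh_hash=mesh_hash,
        )


# -- networks ---------------------------------------------------------------

def save_network_h5(net: RBFNetwork, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("centers", "output_weights", "output_bias", "x_mean", "x_std"):
            f[name] = getattr(net, name)
        f.attrs.update(
            spread=net.spread, y_scale=net.y_scale, mode=net.mode,
            mesh_hash=net.mesh_hash, training_rmse=net.training_rmse,
            sample_norm=net.sample_norm,
        )
        _stamp(f)


def load_network_h5(path) -> RBFNetwork:
    with h5py.File(path, "r") as f:
        return RBFNetwork(
            centers=f["centers"][...],
            spread=float(f.attrs["spread"]),
            output_weights=f["output_weights"][...],
            output_bias=f["output_bias"][...],
            x_mean=f["x_mean"][...],
            x_std=f["x_std"][...],
            y_scale=float(f.attrs["y_scale"]),
            sample_norm=bool(f.attrs["sample_norm"]),
            mode=str(f.attrs["mode"]),
            mesh_hash=str(f.attrs["mesh_hash"]),
            training_rmse=float(f.attrs["training_rmse"]),
        )


# -- datasets ---------------------------------------------------------------

def save_dataset_h5(ds: TrainingDataset, path) -> None:
    from dataclasses import asdict

    with h5py.File(path, "w") as f:
        f["dv_clean"] = ds.dv_clean
        f["gn_clean"] = ds.gn_clean
        f["truth_elements"] = ds.truth_elements
        f["truth_nodes"] = ds.truth_nodes
        if ds.dv_noisy is not None:
            f["dv_noisy"] = ds.dv_noisy
            f["gn_noisy"] = ds.gn_noisy
        meta = {
            "mode": ds.mode,
            "noisy": ds.noisy,
            "mesh_hash": ds.mesh_hash,
            "scenes": [
                {
                    "background_conductivity": s.background_conductivity,
                    "targets": [asdict(t) for t in s.targets],
                }
                for s in ds.scenes
            ],
            "coeffs": [np.asarray(c).tolist() for c in ds.coeffs],
        }
        f.attrs["meta"] = json.dumps(meta)
        _stamp(f)


def load_dataset_h5(path, mesh: Mesh2D | None = None) -> TrainingDataset:
    from eitpost.scenes import PhantomScene, TargetSpec

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        if mesh is not None and mesh.content_hash() != meta["mesh_hash"]:
            raise ValueError("dataset was generated on a different mesh")
        scenes = [
            PhantomScene(
                targets=[TargetSpec(**{**t, "center": tuple(t["center"])}) for t in s["targets"]],
                background_conductivity=s["background_conductivity"],
            )
            for s in meta["scenes"]
        ]
        return TrainingDataset(
            mode=meta["mode"],
            noisy=bool(meta["noisy"]),
            dv_clean=f["dv_clean"][...],
            dv_noisy=f["dv_noisy"][...] if "dv_noisy" in f else None,
            gn_clean=f["gn_clean"][...],
            gn_noisy=f["gn_noisy"][...] if "gn_noisy" in f else None,
            truth_elements=f["truth_elements"][...],
            truth_nodes=f["truth_nodes"][...],
            scenes=scenes,
            coeffs=[np.asarray(c) for c in meta["coeffs"]],
            mesh_hash=meta["mesh_hash"],
            _mesh=mesh,
        )
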