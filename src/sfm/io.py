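"""Readers and writers for matrices, ROI tables and HDF5 scene files.

Square matrices travel as delimited text (tab-separated, one header row of
ROI labels) or as HDF5 datasets; ROI metadata as a delimited table with
columns label, size, x, y, z, hemisphere, homotopic_partner. A full
synthetic scene (connectome + geometry + leadfield) is stored in one HDF5
file under the groups ``/sc``, ``/geometry`` and ``/leadfield``.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .connectome import RawConnectome
from .electromagnetics import Leadfield
from .geometry import ROIGeometry


# ---------------------------------------------------------------- text I/O
def save_matrix_text(path, M: np.ndarray, labels=None) -> None:
    M = np.asarray(M, dtype=float)
    if labels is None:
        labels = [f"roi{i:03d}" for i in range(M.shape[0])]
    pd.DataFrame(M, columns=labels).to_csv(path, sep="\t", index=False)


def load_matrix_text(path):
    """Returns (matrix, labels)."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def save_roi_table(path, geometry: ROIGeometry) -> None:
    pd.DataFrame(
        {
            "label": geometry.labels,
            "size": geometry.sizes,
            "x": geometry.centers[:, 0],
            "y": geometry.centers[:, 1],
            "z": geometry.centers[:, 2],
            "hemisphere": geometry.hemisphere,
            "homotopic_partner": geometry.homotopic,
        }
    ).to_csv(path, sep="\t", index=False)


def load_roi_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- HDF5 I/O
def _write_geometry(f: h5py.File, geometry: ROIGeometry) -> None:
    g = f.require_group("geometry")
    g.create_dataset("centers", data=geometry.centers)
    g.create_dataset("sizes", data=geometry.sizes)
    g.create_dataset("euclid_dist", data=geometry.euclid_dist)
    g.create_dataset("fiber_dist", data=geometry.fiber_dist)
    g.create_dataset("hemisphere", data=np.asarray(geometry.hemisphere, dtype="S1"))
    g.create_dataset("homotopic", data=geometry.homotopic)
    g.create_dataset("labels", data=np.asarray(geometry.labels, dtype="S32"))


def _read_geometry(f: h5py.File) -> ROIGeometry:
    g = f["geometry"]
    return ROIGeometry(
        centers=g["centers"][()],
        sizes=g["sizes"][()],
        euclid_dist=g["euclid_dist"][()],
        fiber_dist=g["fiber_dist"][()],
        hemisphere=g["hemisphere"][()].astype(str),
        homotopic=g["homotopic"][()],
        labels=[s.decode() for s in g["labels"][()]],
    )


def save_connectome_h5(path, raw: RawConnectome, geometry: ROIGeometry = None) -> None:
    with h5py.File(path, "w") as f:
        sc = f.require_group("sc")
        sc.create_dataset("fiber_counts", data=raw.fiber_counts)
        sc.create_dataset("fiber_lengths", data=raw.fiber_lengths)
        sc.create_dataset("roi_sizes", data=raw.roi_sizes)
        if geometry is not None:
            _write_geometry(f, geometry)


def load_connectome_h5(path):
    """Returns (RawConnectome, ROIGeometry or None)."""
    with h5py.File(path, "r") as f:
        raw = RawConnectome(
            fiber_counts=f["sc/fiber_counts"][()],
            roi_sizes=f["sc/roi_sizes"][()],
            fiber_lengths=f["sc/fiber_lengths"][()],
        )
        geometry = _read_geometry(f) if "geometry" in f else None
    return raw, geometry


def save_leadfield_h5(path, leadfield: Leadfield) -> None:
    with h5py.File(path, "w") as f:
        g = f.require_group("leadfield")
        if leadfield.G is not None:
            g.create_dataset("G", data=leadfield.G)
        g.create_dataset("G_fixed", data=leadfield.G_fixed)
        if leadfield.orientations is not None:
            g.create_dataset("orientations", data=leadfield.orientations)


def load_leadfield_h5(path) -> Leadfield:
    with h5py.File(path, "r") as f:
        g = f["leadfield"]
        return Leadfield(
            G=g["G"][()] if "G" in g else None,
            G_fixed=g["G_fixed"][()],
            orientations=g["orientations"][()] if "orientations" in g else None,
        )


def save_scene_h5(path, scene) -> None:
    """Store a SyntheticScene (connectome, geometry, leadfield, seeds)."""
    with h5py.File(path, "w") as f:
        sc = f.require_group("sc")
        sc.create_dataset("fiber_counts", data=scene.raw.fiber_counts)
        sc.create_dataset("fiber_lengths", data=scene.raw.fiber_lengths)
        sc.create_dataset("roi_sizes", data=scene.raw.roi_sizes)
        _write_geometry(f, scene.geometry)
        g = f.require_group("leadfield")
        g.create_dataset("G", data=scene.leadfield.G)
        g.create_dataset("G_fixed", data=scene.leadfield.G_fixed)
        g.create_dataset("orientations", data=scene.leadfield.orientations)
        for key, val in scene.seeds.items():
            f.attrs[f"seed_{key}"] = val
        for key, val in scene.params.items():
            f.attrs[f"param_{key}"] = val


def load_scene_h5(path):
    from .synthetic import SyntheticScene

    with h5py.File(path, "r") as f:
        raw = RawConnectome(
            fiber_counts=f["sc/fiber_counts"][()],
            roi_sizes=f["sc/roi_sizes"][()],
            fiber_lengths=f["sc/fiber_lengths"][()],
        )
        geometry = _read_geometry(f)
        lf = Leadfield(
            G=f["leadfield/G"][()],
            G_fixed=f["leadfield/G_fixed"][()],
            orientations=f["leadfield/orientations"][()],
        )
        seeds = {
            k[len("seed_"):]: int(v) for k, v in f.attrs.items() if k.startswith("seed_")
        }
        params = {
            k[len("param_"):]: v for k, v in f.attrs.items() if k.startswith("param_")
        }
    return SyntheticScene(geometry=geometry, raw=raw, leadfield=lf, params=params, seeds=seeds)


def save_dataset_h5(path, name: str, data: np.ndarray, **attrs) -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=np.asarray(data))
        for k, v in attrs.items():
            ds.attrs[k] = v


def load_dataset_h5(path, name: str) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f[name][()]
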