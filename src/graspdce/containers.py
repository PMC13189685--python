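"""File formats: HDF5 k-space container, NIfTI images/maps, cohort CSV.

The k-space container layout (HDF5):

    /samples       complex128, (n_spokes, n_readout, n_coils)
    /angles        float64, (n_spokes,)          radians
    /timestamps    float64, (n_spokes,)          seconds
    /density_comp  float64, (n_spokes, n_readout)
    /coil_maps     complex128, (n_coils, N, N)   optional
    attrs: tr_seconds, n_partitions, grid_size

Dynamic series go to 4-D NIfTI (x, y, z=1, t) with the frame times and any
provenance recorded in a JSON sidecar; parameter maps to one 2-D/3-D NIfTI
per map.  The cohort table is a flat CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .radial import CoilSensitivities, MultiCoilKSpace, RadialTrajectory
from .recon import DynamicImageSeries

__all__ = [
    "save_kspace",
    "load_kspace",
    "save_dynamic_series",
    "load_dynamic_series",
    "save_map",
    "load_map",
    "cohort_to_csv",
    "cohort_from_csv",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "lesion_id",
    "histology",
    "size_cm",
    "nodal_positive",
    "mvd",
    "ktrans_true",
    "ve_true",
]
FITTED_COLUMNS = ["ktrans_s1", "ve_s1", "ktrans_s2", "ve_s2", "ktrans_final", "ve_final"]


def save_kspace(
    path, kspace: MultiCoilKSpace, coils: CoilSensitivities | None = None
) -> None:
    traj = kspace.trajectory
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=kspace.samples)
        f.create_dataset("angles", data=traj.angles)
        f.create_dataset("timestamps", data=traj.timestamps)
        f.create_dataset("density_comp", data=kspace.density_comp)
        if coils is not None:
            f.create_dataset("coil_maps", data=coils.maps)
        f.attrs["tr_seconds"] = traj.tr_seconds
        f.attrs["n_partitions"] = traj.n_partitions
        f.attrs["n_readout"] = traj.n_readout
        if kspace.grid_size is not None:
            f.attrs["grid_size"] = kspace.grid_size


def load_kspace(path) -> tuple[MultiCoilKSpace, CoilSensitivities | None]:
    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        angles = f["angles"][()]
        timestamps = f["timestamps"][()]
        density = f["density_comp"][()]
        coils = (
            CoilSensitivities(f["coil_maps"][()]) if "coil_maps" in f else None
        )
        tr = float(f.attrs["tr_seconds"])
        n_partitions = int(f.attrs["n_partitions"])
        n_readout = int(f.attrs["n_readout"])
        grid_size = int(f.attrs["grid_size"]) if "grid_size" in f.attrs else None
    radii = (np.arange(n_readout) - n_readout // 2) / n_readout
    kx = radii[None, :] * np.cos(angles)[:, None]
    ky = radii[None, :] * np.sin(angles)[:, None]
    traj = RadialTrajectory(
        n_spokes=angles.size,
        n_readout=n_readout,
        angles=angles,
        k_coords=np.stack([kx, ky], axis=-1),
        timestamps=timestamps,
        tr_seconds=tr,
        n_partitions=n_partitions,
    )
    return (
        MultiCoilKSpace(
            samples=samples, trajectory=traj, density_comp=density, grid_size=grid_size
        ),
        coils,
    )


def _affine(voxel_mm: float) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])


def save_dynamic_series(path, series: DynamicImageSeries, sidecar: dict | None = None):
    """Write magnitude frames as 4-D NIfTI (x, y, z=1, t) plus JSON sidecar."""
    data = np.abs(series.frames).transpose(1, 2, 0)[:, :, None, :]
    img = nib.Nifti1Image(data.astype(np.float64), _affine(series.voxel_size_mm))
    nib.save(img, str(path))
    meta = {"frame_times_s": series.frame_times.tolist(),
            "voxel_size_mm": series.voxel_size_mm}
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_dynamic_series(path) -> DynamicImageSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)[:, :, 0, :].transpose(2, 0, 1)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return DynamicImageSeries(
        frames=data,
        frame_times=np.asarray(meta["frame_times_s"]),
        voxel_size_mm=float(meta["voxel_size_mm"]),
    )


def save_map(path, array: np.ndarray, voxel_mm: float = 1.25) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), _affine(voxel_mm)),
             str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def cohort_to_csv(path, records, fitted: dict | None = None) -> None:
    """Write lesion records (plus fitted columns when given) to CSV."""
    rows = []
    for rec in records:
        row = {c: getattr(rec, c) for c in COHORT_COLUMNS}
        if fitted is not None:
            row.update({c: fitted[rec.lesion_id][c] for c in FITTED_COLUMNS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def cohort_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
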