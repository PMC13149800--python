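"""File formats: HDF5 raw-data container, NIfTI images, CSV tables.

The raw container mirrors a vendor-agnostic free-running acquisition
dump::

    /kspace       complex64, (readouts, samples, coils)
    /trajectory   float64,   (readouts, samples, 3), cycles/voxel
    /timestamps   float64 ms per readout
    /triggers     float64 ms
    /coil_maps    complex64, (coils, nx, ny, nz)
    /ground_truth/diameters, /ground_truth/pressures   (simulation truth)

with scalar attributes (tr_ms, noise_sd, voxel_mm, duration_ms, seed,
and the trajectory's segment layout).  Reconstructed 4D images go to
NIfTI with the voxel size in the header zooms and the cardiac bin width
in the time-per-volume slot.
"""

from __future__ import annotations

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .recon import Image4D
from .synthdata import MModeTrace, PhysioRecord, RawKSpace
from .trajectory import RadialTrajectory, TrajectorySpec

__all__ = [
    "save_raw",
    "load_raw",
    "save_image4d",
    "load_image4d",
    "save_mmode_csv",
    "load_mmode_csv",
]


def save_raw(path, raw: RawKSpace, voxel_mm: float = 0.6, seed: int | None = None) -> None:
    spec = raw.trajectory.spec
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=raw.data.astype(np.complex64))
        traj = f.create_dataset("trajectory", data=raw.trajectory.samples.astype(np.float64))
        traj.attrs["n_segments"] = spec.n_segments
        traj.attrs["readouts_per_segment"] = spec.readouts_per_segment
        from .trajectory import GOLDEN_ANGLE_DEG

        traj.attrs["golden_angle_deg"] = GOLDEN_ANGLE_DEG
        f.create_dataset("timestamps", data=raw.timestamps)
        f.create_dataset("triggers", data=raw.physio.trigger_times)
        f.create_dataset("coil_maps", data=raw.coil_maps.astype(np.complex64))
        g = f.create_group("ground_truth")
        g.create_dataset(
            "diameters", data=raw.ground_truth.get("waveform_diameters_mm", np.empty(0))
        )
        g.attrs["d_d_mm"] = raw.ground_truth.get("d_d_mm", np.nan)
        g.attrs["d_s_mm"] = raw.ground_truth.get("d_s_mm", np.nan)
        g.attrs["rdc_percent"] = raw.ground_truth.get("rdc_percent", np.nan)
        if "pressures" in raw.ground_truth:
            g.create_dataset("pressures", data=np.asarray(raw.ground_truth["pressures"]))
        f.attrs["tr_ms"] = raw.tr_ms
        f.attrs["noise_sd"] = raw.noise_sd
        f.attrs["voxel_mm"] = voxel_mm
        f.attrs["duration_ms"] = raw.physio.duration_ms
        if seed is not None:
            f.attrs["seed"] = seed


def load_raw(path) -> RawKSpace:
    with h5py.File(path, "r") as f:
        samples = f["trajectory"][()]
        tattrs = f["trajectory"].attrs
        spec = TrajectorySpec(
            n_segments=int(tattrs["n_segments"]),
            readouts_per_segment=int(tattrs["readouts_per_segment"]),
            samples_per_readout=samples.shape[1],
        )
        tip = samples[:, -1, :]
        directions = tip / np.linalg.norm(tip, axis=1, keepdims=True)
        trajectory = RadialTrajectory(directions=directions, spec=spec, samples=samples)
        physio = PhysioRecord(f["triggers"][()], float(f.attrs["duration_ms"]))
        gt = {}
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = {k: float(g.attrs[k]) for k in g.attrs}
            if "diameters" in g and g["diameters"].shape[0]:
                gt["waveform_diameters_mm"] = g["diameters"][()]
            if "pressures" in g:
                gt["pressures"] = g["pressures"][()]
        return RawKSpace(
            data=f["kspace"][()].astype(np.complex128),
            timestamps=f["timestamps"][()],
            trajectory=trajectory,
            coil_maps=f["coil_maps"][()].astype(np.complex128),
            tr_ms=float(f.attrs["tr_ms"]),
            noise_sd=float(f.attrs["noise_sd"]),
            physio=physio,
            ground_truth=gt,
        )


def save_image4d(path, image: Image4D) -> None:
    mag = image.magnitude().astype(np.float32)
    affine = np.diag([image.voxel_mm] * 3 + [1.0])
    img = nib.Nifti1Image(mag, affine)
    img.header.set_zooms((image.voxel_mm,) * 3 + (image.bin_width_ms / 1000.0,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)


def load_image4d(path) -> Image4D:
    img = nib.load(path)
    zooms = img.header.get_zooms()
    return Image4D(
        data=np.asarray(img.dataobj, dtype=np.float64),
        voxel_mm=float(zooms[0]),
        bin_width_ms=float(zooms[3]) * 1000.0 if len(zooms) > 3 else float("nan"),
    )


def save_mmode_csv(path, trace: MModeTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.time_s, "upper_mm": trace.upper_mm, "lower_mm": trace.lower_mm}
    ).to_csv(path, index=False)


def load_mmode_csv(path, fps: float = 250.0, imt_mm: float = 0.0) -> MModeTrace:
    df = pd.read_csv(path)
    return MModeTrace(
        time_s=df["time_s"].to_numpy(),
        upper_mm=df["upper_mm"].to_numpy(),
        lower_mm=df["lower_mm"].to_numpy(),
        fps=fps,
        imt_mm=imt_mm,
    )
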