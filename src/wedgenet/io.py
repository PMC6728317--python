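"""File I/O: sinograms as HDF5, images/tomograms as TIFF (PNG accepted on read)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .projection import AngleGrid, Sinogram
from .recon import Tomogram

__all__ = ["save_sinogram", "load_sinogram", "save_tomogram", "load_tomogram",
           "load_image"]


def save_sinogram(path, sino: Sinogram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=sino.values)
        f.create_dataset("angles", data=sino.angle_grid.angles)
        f.create_dataset("mask", data=sino.mask.astype(np.uint8))
        f.attrs["scale"] = sino.scale
        f.attrs["step"] = sino.angle_grid.step


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as f:
        grid = AngleGrid(f["angles"][()], float(f.attrs["step"]))
        return Sinogram(f["values"][()], grid, f["mask"][()].astype(bool),
                        float(f.attrs["scale"]))


def save_tomogram(path, tomo: Tomogram) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("pixels", data=tomo.pixels)
            f.attrs["provenance"] = json.dumps(tomo.provenance, default=str)
    else:
        import tifffile
        tifffile.imwrite(path, tomo.pixels.astype(np.float32),
                         description=json.dumps(tomo.provenance, default=str))


def load_tomogram(path) -> Tomogram:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return Tomogram(f["pixels"][()],
                            json.loads(f.attrs.get("provenance", "{}")))
    import tifffile
    with tifffile.TiffFile(path) as tf:
        prov = {}
        desc = tf.pages[0].tags.get("ImageDescription")
        if desc is not None:
            try:
                prov = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                prov = {}
        return Tomogram(tf.asarray().astype(np.float64), prov)


def load_image(path) -> np.ndarray:
    """Read a grayscale image (TIFF or PNG) as float64 in [0, 1]."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile
        arr = np.asarray(tifffile.imread(path), dtype=np.float64)
    else:
        import imageio.v3 as iio
        arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)
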