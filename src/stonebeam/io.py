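"""File formats for the pipeline: HDF5 channel data, TIFF/PNG images,
manifest and metrics CSV.

Channel data round-trips bit-exactly (float32 samples plus acquisition
attributes).  Linear images are written as float32 TIFF (the measurement
format); log-compressed PNGs are display-only exports.
"""

from __future__ import annotations

import json
import pathlib

import h5py
import numpy as np
import pandas as pd
import tifffile

from .acquisition import AcquisitionConfig, linear_array
from .beamform import BeamformedImage, ImageGrid, envelope_logcompress
from .exceptions import InvalidParameterError
from .synthetic_scene import ChannelData

__all__ = [
    "write_channel_h5",
    "read_channel_h5",
    "write_image_tiff",
    "read_image_tiff",
    "write_image_png",
    "write_manifest",
    "read_manifest",
    "write_metrics_csv",
]


def write_channel_h5(path, data: ChannelData) -> pathlib.Path:
    """One acquisition per file: /channel_data (n_angles, n_el, n_t) float32
    plus every attribute needed to beamform it back."""
    path = pathlib.Path(path)
    cfg = data.config
    with h5py.File(path, "w") as f:
        d = f.create_dataset("channel_data", data=np.asarray(data.samples, np.float32))
        d.attrs["t0"] = float(data.t0)
        d.attrs["fs"] = float(data.fs)
        d.attrs["f0"] = float(cfg.f0)
        d.attrs["n_cycles"] = float(cfg.n_cycles)
        d.attrs["c"] = float(cfg.c)
        d.attrs["depth_max"] = float(cfg.depth_max)
        d.attrs["seed"] = int(cfg.seed)
        d.attrs["angles_deg"] = np.asarray(cfg.angles_deg, float)
        d.attrs["element_x"] = np.asarray(cfg.geometry.element_x, float)
        d.attrs["pitch"] = float(cfg.geometry.pitch)
        d.attrs["element_width"] = float(cfg.geometry.element_width)
    return path


def read_channel_h5(path) -> ChannelData:
    with h5py.File(path, "r") as f:
        if "channel_data" not in f:
            raise InvalidParameterError(f"{path}: missing /channel_data dataset")
        d = f["channel_data"]
        a = dict(d.attrs)
        samples = d[...]
    geom_x = np.asarray(a["element_x"], float)
    pitch = float(a["pitch"])
    geometry = linear_array(n_elements=geom_x.size, pitch=pitch,
                            element_width=float(a["element_width"]))
    if not np.allclose(geometry.element_x, geom_x, atol=1e-12):
        raise InvalidParameterError(f"{path}: element positions are not a centred uniform array")
    cfg = AcquisitionConfig(geometry=geometry,
                            angles_deg=np.asarray(a["angles_deg"], float),
                            f0=float(a["f0"]), n_cycles=float(a["n_cycles"]),
                            fs=float(a["fs"]), c=float(a["c"]),
                            depth_max=float(a["depth_max"]), seed=int(a["seed"]))
    return ChannelData(samples=samples, t0=float(a["t0"]), fs=float(a["fs"]),
                       config=cfg)


def write_image_tiff(path, image: BeamformedImage) -> pathlib.Path:
    """Linear-scale float32 TIFF; grid axes and params in the image description."""
    path = pathlib.Path(path)
    meta = {"method": image.method,
            "params": {k: (v if v is None or isinstance(v, (int, float, str, bool))
                           else float(v)) for k, v in image.params.items()},
            "x_m": list(map(float, image.grid.x)),
            "z_m": list(map(float, image.grid.z))}
    tifffile.imwrite(path, image.values.astype(np.float32),
                     description=json.dumps(meta))
    return path


def read_image_tiff(path) -> BeamformedImage:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        desc = page.description
        values = page.asarray()
    try:
        meta = json.loads(desc)
        grid = ImageGrid(x=np.asarray(meta["x_m"], float),
                         z=np.asarray(meta["z_m"], float))
    except (json.JSONDecodeError, KeyError) as exc:
        raise InvalidParameterError(f"{path}: missing or invalid image metadata") from exc
    return BeamformedImage(grid=grid, values=np.asarray(values, float),
                           method=meta.get("method", "unknown"),
                           params=meta.get("params", {}))


def write_image_png(path, image: BeamformedImage, dynamic_range_dB: float = 60.0) -> pathlib.Path:
    """8-bit grayscale PNG of the log-compressed image (display only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = pathlib.Path(path)
    db = envelope_logcompress(image, dynamic_range_dB)
    extent = [image.grid.x[0] * 1e3, image.grid.x[-1] * 1e3,
              image.grid.z[-1] * 1e3, image.grid.z[0] * 1e3]
    fig, ax = plt.subplots(figsize=(4.5, 4.0))
    im = ax.imshow(db, cmap="gray", vmin=-dynamic_range_dB, vmax=0.0,
                   extent=extent, aspect="equal")
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("depth (mm)")
    ax.set_title(image.method)
    fig.colorbar(im, ax=ax, label="dB")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def write_manifest(path, entries: list) -> pathlib.Path:
    """JSON manifest: one entry per phantom with file name, seed and scene
    truth (including the true stone width for later reference)."""
    path = pathlib.Path(path)
    path.write_text(json.dumps({"entries": entries}, indent=2, sort_keys=True))
    return path


def read_manifest(path) -> list:
    path = pathlib.Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InvalidParameterError(f"{path}: manifest is not valid JSON") from exc
    if not isinstance(doc, dict) or "entries" not in doc:
        raise InvalidParameterError(f"{path}: manifest missing 'entries'")
    return doc["entries"]


def write_metrics_csv(path, records: pd.DataFrame) -> pathlib.Path:
    path = pathlib.Path(path)
    records.to_csv(path, index=False)
    return path
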