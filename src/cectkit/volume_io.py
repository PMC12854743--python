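"""Reading and writing attenuation volumes.

Volumes travel as multi-page TIFF stacks (one page per depth slice) together
with a YAML sidecar.  TIFF tags are unreliable across μCT vendors, so the
sidecar is the single source of truth for the voxel size and any acquisition
metadata (bath attenuation, immersion time, RNG seed of a synthetic volume).

Axis convention, fixed package-wide: arrays are indexed ``(z, y, x)`` with
0-based indices; after surface alignment ``z`` increases from the articular
surface into the subchondral bone.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml

__all__ = ["AttenuationVolume", "read_volume", "write_volume", "sidecar_path"]


@dataclass
class AttenuationVolume:
    """A 3D attenuation grid in Hounsfield-like units.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Attenuation values (HU), stored as float32.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres.
    meta : dict
        Free-form acquisition metadata (e.g. ``time_h``, ``bath_hu``,
        ``seed``, ``medium``); round-tripped through the YAML sidecar.
    """

    values: np.ndarray
    voxel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x); got ndim={self.values.ndim}")
        if min(self.values.shape) < 1 or self.values.size == 0:
            raise ValueError("volume must have at least one voxel along every axis")
        if not np.isfinite(self.voxel_size_um) or self.voxel_size_um <= 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite attenuation values")
        if self.values.dtype != np.float32:
            self.values = self.values.astype(np.float32)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0


def sidecar_path(path: str) -> str:
    """YAML sidecar path associated with a TIFF stack path."""
    base, _ = os.path.splitext(path)
    return base + ".yaml"


def write_volume(volume: AttenuationVolume, path: str, mode: str = "float32") -> str:
    """Write a volume as a multi-page TIFF stack plus YAML sidecar.

    ``mode="float32"`` is lossless for the in-memory representation
    (``read(write(v)) == v`` bit-for-bit).  ``mode="uint16"`` scales values
    onto the 16-bit range and records ``scale``/``offset`` in the sidecar;
    the quantization error is bounded by ``scale / 2``.

    Returns the sidecar path.
    """
    if not isinstance(volume, AttenuationVolume):
        raise TypeError("write_volume expects an AttenuationVolume")
    meta = dict(volume.meta)
    meta["axis_order"] = "zyx"
    meta["voxel_size_um"] = float(volume.voxel_size_um)
    meta["mode"] = mode
    if mode == "float32":
        data = volume.values
    elif mode == "uint16":
        vmin = float(volume.values.min())
        vmax = float(volume.values.max())
        scale = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
        data = np.round((volume.values - vmin) / scale).astype(np.uint16)
        meta["scale"] = scale
        meta["offset"] = vmin
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'float32' or 'uint16'")
    tifffile.imwrite(path, data)
    side = sidecar_path(path)
    with open(side, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return side


def read_volume(path: str, meta_path: str | None = None) -> AttenuationVolume:
    """Read a TIFF stack and its YAML sidecar back into an AttenuationVolume.

    Raises with an explicit message when the sidecar or the voxel size is
    missing: a volume without a physical scale cannot be analysed.
    """
    if meta_path is None:
        meta_path = sidecar_path(path)
    if not os.path.exists(meta_path):
        raise FileNotFoundError(
            f"metadata sidecar {meta_path!r} not found: the voxel size is unknown "
            "and the volume cannot be interpreted"
        )
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    if "voxel_size_um" not in meta:
        raise ValueError(f"sidecar {meta_path!r} is missing the required key 'voxel_size_um'")
    voxel = float(meta.pop("voxel_size_um"))
    data = tifffile.imread(path)
    if data.ndim == 2:  # single-page stack
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"TIFF stack {path!r} has inconsistent slice dimensions (ndim={data.ndim})")
    mode = meta.pop("mode", "float32")
    meta.pop("axis_order", None)
    if mode == "uint16":
        scale = float(meta.pop("scale"))
        offset = float(meta.pop("offset"))
        values = data.astype(np.float64) * scale + offset
    else:
        values = data.astype(np.float32)
    return AttenuationVolume(values=values, voxel_size_um=voxel, meta=meta)
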