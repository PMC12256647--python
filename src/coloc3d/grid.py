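"""Voxel-grid container and TIFF + YAML sidecar I/O.

A grid stores a multichannel 3D intensity stack indexed (channel, z, y, x)
together with its physical voxel spacing in μm. On disk the stack is a
multi-page TIFF in channel-major, Z-page order, with channel names and
spacing recorded in a YAML sidecar next to it (confocal exports rarely carry
reliable spacing metadata, so the sidecar is authoritative).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["VoxelGrid", "read_grid", "write_grid"]


@dataclass
class VoxelGrid:
    """Multichannel 3D intensity array with physical voxel spacing.

    ``data``: float array of shape (n_channels, nz, ny, nx).
    ``spacing``: (z, y, x) voxel spacing in μm, strictly positive.
    ``channels``: channel names, same order as the first axis.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("grid data must have shape (channel, z, y, x)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel names must match the first data axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def channel(self, name: str) -> np.ndarray:
        """The 3D (z, y, x) stack for one named channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in grid (have {list(self.channels)})"
            ) from None
        return self.data[idx]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".yaml")


def write_grid(grid: VoxelGrid, tiff_path: str | Path) -> Path:
    """Write a grid as a multi-page TIFF (channel-major, Z-page order) plus a
    YAML sidecar recording spacing and channel names. Returns the sidecar path."""
    tiff_path = Path(tiff_path)
    pages = grid.data.reshape(-1, *grid.data.shape[2:]).astype(np.float32)
    tifffile.imwrite(tiff_path, pages)
    sidecar = _sidecar_path(tiff_path)
    meta = {
        "spacing_um_zyx": [float(s) for s in grid.spacing],
        "channels": list(grid.channels),
        "n_z": int(grid.data.shape[1]),
    }
    sidecar.write_text(yaml.safe_dump(meta))
    return sidecar


def read_grid(tiff_path: str | Path) -> VoxelGrid:
    """Read a grid written by :func:`write_grid` (TIFF + YAML sidecar)."""
    tiff_path = Path(tiff_path)
    sidecar = _sidecar_path(tiff_path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing spacing sidecar {sidecar} for {tiff_path}"
        )
    meta = yaml.safe_load(sidecar.read_text())
    spacing = tuple(float(s) for s in meta["spacing_um_zyx"])
    channels = tuple(meta["channels"])
    n_z = int(meta["n_z"])
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    data = pages.reshape(len(channels), n_z, *pages.shape[1:])
    return VoxelGrid(data=data, spacing=spacing, channels=channels)
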