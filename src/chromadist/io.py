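"""Stack and table input/output, plus the package-wide coordinate convention.

Conventions
-----------
* Intensity arrays are indexed ``(z, y, x)``.
* All positions handed between modules are *physical* coordinates in
  nanometers, ordered ``(x, y, z)``.  Voxel indices appear only at the IO
  boundary; the anisotropic confocal voxel (lateral ~104 nm, axial 250 nm)
  makes voxel-space geometry meaningless.
* The physical origin is the center of voxel ``(0, 0, 0)``, 0-based: voxel
  ``(iz, iy, ix)`` has its center at ``(ix*vx, iy*vy, iz*vz)`` nm.
* The configured voxel size always overrides file metadata (TIFF resolution
  tags are unreliable across acquisition software).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: Default confocal voxel size in nm, (x, y, z).
DEFAULT_VOXEL_SIZE_NM: tuple[float, float, float] = (103.8, 103.8, 250.0)

#: Column order of centroid tables.
CENTROID_COLUMNS = [
    "image_id",
    "channel",
    "x_nm",
    "y_nm",
    "z_nm",
    "quality",
    "nucleus_label",
    "source",
]

#: Column order of pair tables.  ``a`` is the reference channel, ``b`` the
#: moving channel; coordinates are physical nm.
PAIR_COLUMNS = [
    "image_id",
    "ax_nm",
    "ay_nm",
    "az_nm",
    "bx_nm",
    "by_nm",
    "bz_nm",
    "raw_distance_nm",
    "nucleus_label",
]


@dataclass
class VoxelGrid3D:
    """One channel's 3D intensity stack with its physical voxel size.

    Parameters
    ----------
    intensities
        Non-negative reals, indexed ``(z, y, x)``.
    voxel_size_nm
        Physical voxel size in nm, ordered ``(x, y, z)``.
    channel_label
        Free-text channel name.
    """

    intensities: np.ndarray
    voxel_size_nm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D (z, y, x); got ndim={self.intensities.ndim}"
            )
        if any(s < 1 for s in self.intensities.shape):
            raise ValueError("intensity array needs >= 1 plane per axis")
        vs = tuple(float(v) for v in self.voxel_size_nm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be 3 strictly positive reals; got {vs}")
        self.voxel_size_nm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def physical_extent_nm(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) in nm spanned by voxel centers."""
        nz, ny, nx = self.intensities.shape
        vx, vy, vz = self.voxel_size_nm
        return ((nx - 1) * vx, (ny - 1) * vy, (nz - 1) * vz)


def voxel_to_physical(
    index: Sequence[float] | np.ndarray,
    voxel_size_nm: Sequence[float],
) -> np.ndarray:
    """Convert voxel indices ``(z, y, x)`` to physical nm points ``(x, y, z)``.

    Accepts a single triple or an ``(n, 3)`` array. Fractional indices are
    allowed (sub-voxel positions).
    """
    idx = np.atleast_2d(np.asarray(index, dtype=float))
    vx, vy, vz = voxel_size_nm
    out = np.column_stack([idx[:, 2] * vx, idx[:, 1] * vy, idx[:, 0] * vz])
    return out[0] if np.asarray(index).ndim == 1 else out


def physical_to_voxel(
    point_nm: Sequence[float] | np.ndarray,
    voxel_size_nm: Sequence[float],
) -> np.ndarray:
    """Convert physical nm points ``(x, y, z)`` to fractional voxel indices ``(z, y, x)``."""
    pts = np.atleast_2d(np.asarray(point_nm, dtype=float))
    vx, vy, vz = voxel_size_nm
    out = np.column_stack([pts[:, 2] / vz, pts[:, 1] / vy, pts[:, 0] / vx])
    return out[0] if np.asarray(point_nm).ndim == 1 else out


def load_stack(
    path: str | Path,
    channel_map: Mapping[int, str],
    voxel_size_nm: Sequence[float] = DEFAULT_VOXEL_SIZE_NM,
    axis_order: str = "CZYX",
) -> list[VoxelGrid3D]:
    """Read a multi-channel 3D stack from a multi-page TIFF.

    Parameters
    ----------
    path
        TIFF file holding grayscale planes.
    channel_map
        Mapping from channel index in the file to a channel label; one
        :class:`VoxelGrid3D` is returned per entry, in ascending index order.
    voxel_size_nm
        Physical voxel size ``(x, y, z)`` in nm.  Always wins over any file
        metadata.
    axis_order
        On-disk plane layout, ``"CZYX"`` or ``"ZCYX"``.  4D arrays are
        reordered accordingly; a 3D array is treated as single-channel.

    Returns
    -------
    list of VoxelGrid3D, axis order normalized to ``(z, y, x)``.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    axis_order = axis_order.upper()
    if axis_order not in ("CZYX", "ZCYX"):
        raise ValueError(f"axis_order must be CZYX or ZCYX, got {axis_order!r}")

    if data.ndim == 3:
        data = data[np.newaxis]  # single channel -> CZYX
    elif data.ndim == 4:
        if axis_order == "ZCYX":
            data = np.swapaxes(data, 0, 1)
    else:
        raise ValueError(f"expected 3D or 4D TIFF data, got ndim={data.ndim}")

    n_channels = data.shape[0]
    grids: list[VoxelGrid3D] = []
    for idx in sorted(channel_map):
        if not 0 <= idx < n_channels:
            raise IndexError(
                f"channel index {idx} out of range for {n_channels}-channel file"
            )
        grids.append(
            VoxelGrid3D(
                intensities=np.asarray(data[idx]),
                voxel_size_nm=tuple(voxel_size_nm),
                channel_label=channel_map[idx],
            )
        )
    return grids


def save_stack(
    path: str | Path,
    grids: Sequence[VoxelGrid3D],
    axis_order: str = "CZYX",
) -> None:
    """Write channels as a multi-page TIFF in the requested plane order."""
    axis_order = axis_order.upper()
    if axis_order not in ("CZYX", "ZCYX"):
        raise ValueError(f"axis_order must be CZYX or ZCYX, got {axis_order!r}")
    stack = np.stack([g.intensities for g in grids], axis=0)  # CZYX
    if axis_order == "ZCYX":
        stack = np.swapaxes(stack, 0, 1)
    tifffile.imwrite(Path(path), stack)


def empty_centroid_table() -> pd.DataFrame:
    return pd.DataFrame(columns=CENTROID_COLUMNS)


def empty_pair_table() -> pd.DataFrame:
    return pd.DataFrame(columns=PAIR_COLUMNS)


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    allow_empty: bool = False,
) -> None:
    """Write a result table (centroids, pairs, distances, summaries) as CSV.

    Comma-separated, '.' decimal, UTF-8, one header row.  Floats are written
    at full repr precision so a read-back round trip is value-exact.
    """
    if len(table) == 0 and not allow_empty:
        raise ValueError("refusing to write an empty table without allow_empty=True")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_centroids(path: str | Path) -> pd.DataFrame:
    """Read a centroid CSV (columns as in :data:`CENTROID_COLUMNS`)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"image_id", "channel", "x_nm", "y_nm", "z_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"centroid table missing columns: {sorted(missing)}")
    for col, default in (("quality", np.nan), ("nucleus_label", 0), ("source", "external")):
        if col not in df.columns:
            df[col] = default
    return df[CENTROID_COLUMNS]


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(PAIR_COLUMNS) - {"nucleus_label"} - set(df.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    if "nucleus_label" not in df.columns:
        df["nucleus_label"] = 0
    return df[PAIR_COLUMNS]
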