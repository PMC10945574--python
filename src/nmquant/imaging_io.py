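"""Calibrated multichannel volume and table I/O.

Single source of truth for axis order and calibration conventions:

* In-memory volumes are 4-D arrays ordered ``(channel, z, y, x)``.
* ``voxel_size_um`` is given in ``(x, y, z)`` order (the order microscope
  metadata uses), all entries in micrometres.
* Voxel indexing is 0-based; the world position of voxel ``(k, j, i)`` is
  the voxel centre ``(i * vx, j * vy, k * vz)`` in micrometres.

Volumes are written as OME-TIFF with physical pixel sizes and channel names
recorded in the metadata, and round-trip bit-identically.
"""

from __future__ import annotations

import dataclasses
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: channel roles understood by the analyses
KNOWN_ROLES = ("fiber", "btx", "gfp", "chat", "bIII")


class CalibrationError(ValueError):
    """Raised when voxel/pixel calibration is missing or invalid."""


class AxisOrderError(ValueError):
    """Raised when the axis order of a TIFF cannot be determined."""


@dataclass
class VolumeImage:
    """A calibrated multichannel 3-D raster.

    Parameters
    ----------
    data:
        4-D array ordered ``(channel, z, y, x)``; intensities must be
        non-negative.
    voxel_size_um:
        Physical voxel size ``(x, y, z)`` in micrometres, all positive.
    channel_roles:
        Maps a semantic role (``fiber``, ``btx``, ``gfp``, ``chat``,
        ``bIII``) to a channel index.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (c, z, y, x) data, got ndim={self.data.ndim}")
        vx, vy, vz = self.voxel_size_um
        if not (vx > 0 and vy > 0 and vz > 0):
            raise CalibrationError(f"voxel sizes must be positive, got {self.voxel_size_um}")
        self.voxel_size_um = (float(vx), float(vy), float(vz))
        n_chan = self.data.shape[0]
        indices = list(self.channel_roles.values())
        if len(set(indices)) != len(indices):
            raise ValueError(f"channel_roles indices must be distinct: {self.channel_roles}")
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n_chan:
                raise ValueError(f"role {role!r} maps to channel {idx}, but volume has {n_chan} channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` array for a named role."""
        if role not in self.channel_roles:
            raise KeyError(f"volume has no channel with role {role!r}; roles: {sorted(self.channel_roles)}")
        return self.data[self.channel_roles[role]]

    def world_extent_um(self) -> tuple[float, float, float]:
        """Extent ``(x, y, z)`` in micrometres spanned by voxel centres."""
        nz, ny, nx = self.shape_zyx
        vx, vy, vz = self.voxel_size_um
        return ((nx - 1) * vx, (ny - 1) * vy, (nz - 1) * vz)


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write a :class:`VolumeImage` to OME-TIFF, recording calibration and roles."""
    path = Path(path)
    role_by_index = {idx: role for role, idx in vol.channel_roles.items()}
    names = [role_by_index.get(i, f"channel{i}") for i in range(vol.n_channels)]
    vx, vy, vz = vol.voxel_size_um
    tifffile.imwrite(
        path,
        vol.data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": vx,
            "PhysicalSizeY": vy,
            "PhysicalSizeZ": vz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": names},
        },
    )


def _voxel_size_from_ome(ome_xml: str) -> tuple[float, float, float] | None:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    for elem in root.iter():
        if elem.tag.endswith("Pixels"):
            try:
                return (
                    float(elem.attrib["PhysicalSizeX"]),
                    float(elem.attrib["PhysicalSizeY"]),
                    float(elem.attrib["PhysicalSizeZ"]),
                )
            except KeyError:
                return None
    return None


def read_volume(
    path: str | Path,
    role_map: Mapping[str, int],
    voxel_size_um: tuple[float, float, float] | None = None,
    axes: str | None = None,
) -> VolumeImage:
    """Read a TIFF/OME-TIFF volume into canonical ``(c, z, y, x)`` order.

    Voxel size is taken from OME metadata when present; otherwise
    ``voxel_size_um`` must be given explicitly (``(x, y, z)`` µm). A missing
    calibration is an error — 1 µm is never silently assumed.

    ``axes`` overrides the axis order detected from the file for plain TIFFs
    whose axes tifffile cannot name (accepted: permutations of C, Z, Y, X).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        detected = series.axes
        ome_size = _voxel_size_from_ome(tif.ome_metadata) if tif.is_ome else None

    order = axes if axes is not None else detected
    order = order.upper()
    if set(order) <= {"C", "Z", "Y", "X"} and order.endswith("YX") and len(order) == data.ndim:
        if "C" not in order:
            data = data[np.newaxis]
            order = "C" + order
        if "Z" not in order:
            data = data[:, np.newaxis] if order[0] == "C" else data[np.newaxis]
            order = order[0] + "Z" + order[1:] if order[0] == "C" else "Z" + order
        data = np.transpose(data, [order.index(a) for a in "CZYX"])
    else:
        raise AxisOrderError(
            f"cannot interpret axis order {detected!r} of {path.name}; "
            "pass axes= with a permutation of C, Z, Y, X"
        )

    size = ome_size if ome_size is not None else voxel_size_um
    if size is None:
        raise CalibrationError(
            f"{path.name} carries no physical pixel size and no voxel_size_um override was given"
        )

    n_chan = data.shape[0]
    for role, idx in role_map.items():
        if not 0 <= idx < n_chan:
            raise ValueError(
                f"role map requests channel {idx} for {role!r}, but file has {n_chan} channel(s)"
            )
    return VolumeImage(data=data, voxel_size_um=tuple(size), channel_roles=dict(role_map))


def _records_to_frame(records: Sequence) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, Mapping):
            rows.append(dict(rec))
        else:
            raise TypeError(f"cannot serialise record of type {type(rec).__name__}")
    if rows:
        return pd.DataFrame(rows, columns=list(rows[0].keys()))
    return pd.DataFrame()


def write_table(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write records (dataclasses, dicts or a DataFrame) to CSV.

    Column order is stable (field order of the first record). Non-finite
    area values are rejected: a NaN/inf CSA is always an upstream bug.
    """
    frame = _records_to_frame(records)
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    for col in frame.columns:
        if col.endswith("_um2") or col.endswith("_um3"):
            vals = pd.to_numeric(frame[col], errors="coerce")
            if len(vals) and not np.isfinite(vals.to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite values in column {col!r}")
    frame.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV table written by :func:`write_table`."""
    return pd.read_csv(path)
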