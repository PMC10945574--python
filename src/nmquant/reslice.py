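"""3-D reconstruction support: fibre-axis estimation and digital reslicing.

The core of the digital cross-sectional-area workflow is to treat the
confocal stack through a thick longitudinal section as a calibrated 3-D
volume, estimate the local muscle-fibre axis, and extract a virtual plane
*transverse* to that axis, on which CSA can be measured without the
foreshortening bias of the physical section plane.

All geometry is done in physical micrometre coordinates; anisotropic voxels
are handled by mapping world positions to fractional voxel indices at the
moment of interpolation, never by resampling the stack to isotropic first.
Samples falling outside the volume are marked missing (NaN), not zero-filled,
so they can be excluded from downstream area measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .imaging_io import VolumeImage


class DegenerateOrientationError(ValueError):
    """Raised when the structure tensor has no dominant orientation."""


@dataclass
class PlaneImage:
    """A resliced 2-D multichannel image; NaN pixels are outside the volume."""

    data: np.ndarray  # (c, h, w), float, NaN = missing
    pixel_size_um: float
    channel_roles: dict[str, int] = field(default_factory=dict)

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channel_roles:
            raise KeyError(f"plane has no channel with role {role!r}")
        return self.data[self.channel_roles[role]]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.data[0])


@dataclass
class ReslicePlane:
    """An oriented, calibrated sampling plane in world (µm) coordinates.

    ``origin_um`` is the centre of the sampled rectangle; ``normal`` the
    plane normal (for transverse reslicing: the local fibre axis);
    ``basis_u``/``basis_v`` span the plane. All vectors are (x, y, z).
    """

    origin_um: np.ndarray
    normal: np.ndarray
    basis_u: np.ndarray
    basis_v: np.ndarray
    extent_um: tuple[float, float]  # (width along u, height along v)
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.basis_u = np.asarray(self.basis_u, dtype=float)
        self.basis_v = np.asarray(self.basis_v, dtype=float)
        frame = np.stack([self.normal, self.basis_u, self.basis_v])
        if not np.allclose(frame @ frame.T, np.eye(3), atol=1e-9):
            raise ValueError("{normal, basis_u, basis_v} must be orthonormal to 1e-9")
        if self.extent_um[0] <= 0 or self.extent_um[1] <= 0 or self.pixel_size_um <= 0:
            raise ValueError("extent and pixel size must be > 0")

    @classmethod
    def from_normal(
        cls,
        origin_um,
        normal,
        extent_um: tuple[float, float],
        pixel_size_um: float,
    ) -> "ReslicePlane":
        """Build a plane from a normal, choosing a deterministic in-plane basis.

        ``basis_u`` is the unit projection of +y onto the plane (falling back
        to +z when the normal is parallel to y), ``basis_v = normal x u``.
        """
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        ref = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(ref, n)) > 1.0 - 1e-6:
            ref = np.array([0.0, 0.0, 1.0])
        u = ref - np.dot(ref, n) * n
        u = u / np.linalg.norm(u)
        v = np.cross(n, u)
        return cls(np.asarray(origin_um, float), n, u, v, tuple(extent_um), float(pixel_size_um))

    def grid_points_um(self) -> tuple[np.ndarray, tuple[int, int]]:
        """World coordinates of every plane pixel centre; returns (points, (h, w))."""
        w_um, h_um = self.extent_um
        nw = max(1, int(round(w_um / self.pixel_size_um)))
        nh = max(1, int(round(h_um / self.pixel_size_um)))
        su = (np.arange(nw) - (nw - 1) / 2) * self.pixel_size_um
        sv = (np.arange(nh) - (nh - 1) / 2) * self.pixel_size_um
        svv, suu = np.meshgrid(sv, su, indexing="ij")
        pts = (
            self.origin_um[np.newaxis, np.newaxis, :]
            + suu[..., np.newaxis] * self.basis_u[np.newaxis, np.newaxis, :]
            + svv[..., np.newaxis] * self.basis_v[np.newaxis, np.newaxis, :]
        )
        return pts, (nh, nw)


def estimate_fiber_axis(
    vol: VolumeImage,
    roi: tuple[slice, slice, slice] | None = None,
    smooth_sigma_px: float = 1.0,
    degeneracy_tol: float = 1e-3,
) -> np.ndarray:
    """Estimate the dominant fibre orientation in a ROI of the fibre channel.

    Uses structure-tensor eigenanalysis: gradients are taken with physical
    µm spacing (anisotropy-corrected), their averaged outer product is
    eigendecomposed, and the eigenvector of the smallest eigenvalue — the
    direction of least intensity variation — is the fibre axis. The sign is
    fixed to a positive x component (ties broken toward +y, then +z).

    Returns a unit (x, y, z) vector. Raises
    :class:`DegenerateOrientationError` for isotropic/empty ROIs.
    """
    data = vol.channel("fiber").astype(float)
    if roi is not None:
        data = data[roi]
    if data.size == 0:
        raise ValueError("ROI is empty")
    vx, vy, vz = vol.voxel_size_um
    if smooth_sigma_px > 0:
        data = ndi.gaussian_filter(data, smooth_sigma_px)
    gz, gy, gx = np.gradient(data, vz, vy, vx)
    grads = np.stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tensor = grads @ grads.T / grads.shape[1]
    trace = np.trace(tensor)
    if trace <= 0 or not np.isfinite(trace):
        raise DegenerateOrientationError(
            "no intensity variation in ROI; use a larger ROI containing fibre boundaries"
        )
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    if (evals[1] - evals[0]) / trace < degeneracy_tol:
        raise DegenerateOrientationError(
            "structure tensor is degenerate (no dominant orientation); use a larger ROI"
        )
    axis = evecs[:, 0]
    for comp in range(3):
        if abs(axis[comp]) > 1e-12:
            if axis[comp] < 0:
                axis = -axis
            break
    return axis / np.linalg.norm(axis)


def _sample_plane(
    data_zyx: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    plane: ReslicePlane,
    order: int = 1,
    fill: float = np.nan,
) -> np.ndarray:
    pts, (nh, nw) = plane.grid_points_um()
    vx, vy, vz = voxel_size_um
    coords = np.stack(
        [pts[..., 2] / vz, pts[..., 1] / vy, pts[..., 0] / vx]
    )  # fractional (z, y, x) indices
    # the volume domain is the voxel-centre hull [0, n-1] per axis; points
    # outside it are missing. Sampling uses mode='nearest' so that boundary
    # pixels are not contaminated by the fill value, then masks explicitly.
    tol = 1e-9
    outside = np.zeros((nh, nw), dtype=bool)
    for ax, n_ax in enumerate(data_zyx.shape):
        outside |= (coords[ax] < -tol) | (coords[ax] > n_ax - 1 + tol)
    out = ndi.map_coordinates(
        data_zyx.astype(float), coords.reshape(3, -1), order=order, mode="nearest"
    ).reshape(nh, nw)
    out[outside] = fill
    return out


def reslice_volume(vol: VolumeImage, plane: ReslicePlane) -> PlaneImage:
    """Extract a virtual plane by trilinear interpolation in µm space.

    Pixels outside the volume are NaN (missing). Raises ``ValueError`` if
    the plane misses the volume entirely.
    """
    out = np.stack(
        [_sample_plane(vol.data[c], vol.voxel_size_um, plane) for c in range(vol.n_channels)]
    )
    if np.isnan(out).all():
        raise ValueError("reslice plane lies entirely outside the volume")
    return PlaneImage(out, plane.pixel_size_um, dict(vol.channel_roles))


def reslice_labels(
    label_volume: np.ndarray, voxel_size_um: tuple[float, float, float], plane: ReslicePlane
) -> np.ndarray:
    """Nearest-neighbour reslice of an integer label volume (0 = outside)."""
    out = _sample_plane(label_volume, voxel_size_um, plane, order=0, fill=0.0)
    return out.astype(label_volume.dtype)


def transverse_plane_through(
    vol: VolumeImage,
    axis: np.ndarray,
    x_um: float | None = None,
    pixel_size_um: float | None = None,
    extent_pad_um: float = 2.0,
) -> ReslicePlane:
    """A plane perpendicular to ``axis`` through the volume at position x.

    Convenience for the common case of quasi-x-aligned fibres: the plane is
    centred laterally/axially on the volume, at ``x_um`` along x (default:
    volume centre), sized to cover the full y and z extent.
    """
    ex, ey, ez = vol.world_extent_um()
    if x_um is None:
        x_um = ex / 2
    if pixel_size_um is None:
        pixel_size_um = min(vol.voxel_size_um[1], vol.voxel_size_um[2])
    origin = np.array([x_um, ey / 2, ez / 2])
    return ReslicePlane.from_normal(
        origin, axis, (ey + 2 * extent_pad_um, ez + 2 * extent_pad_um), pixel_size_um
    )
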