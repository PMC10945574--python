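"""Ground-truthed synthetic phantoms for the neuromuscular analyses.

Three generators emulate the three data modalities the toolkit quantifies:

``generate_muscle_phantom``
    A 4-channel confocal-like z-stack through a 30-µm-thick longitudinal
    muscle section: quasi-parallel elliptical fibres (fibre-fill channel)
    with class-dependent cross-sectional areas, α-bungarotoxin endplate
    blobs, and GFP/YFP (graft axon) and ChAT (all motor axon) marker tubes.
    Innervation classes follow the four-way taxonomy: *graft* (endplate
    overlapped by a GFP⁺ terminal), *endogenous* (ChAT⁺ GFP⁻ terminal),
    *denervated* (bare endplate) and *unconfirmed* (endplate outside the
    scanned region — no endplate is drawn for these fibres).

``generate_nerve_phantom``
    A 2-channel nerve cross-section: packed non-overlapping axon discs with
    a bimodal (lognormal-mixture) calibre distribution; all axons appear in
    the βIII-tubulin channel, the motor subset also in the ChAT channel.

``generate_force_trace``
    An isometric force trace: motor units with individual twitch forces and
    recruitment thresholds, alpha-function twitch kernel, tetanic fusion
    gain at ≥20 Hz, exponential fatigue envelope, additive Gaussian noise.

Every generator records analytic ground truth (ellipse/disc areas, class
labels, unit counts) so downstream measurements can be tested against
closed-form values. One integer seed drives all randomness; identical
spec + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imaging_io import VolumeImage

#: innervation classes in reporting order
CLASS_NAMES = ("graft", "endogenous", "denervated", "unconfirmed")

#: class proportions of the reference muscle (62, 13, 28 and 117 of 220 fibres)
DEFAULT_CLASS_FRACTIONS = {
    "graft": 62 / 220,
    "endogenous": 13 / 220,
    "denervated": 28 / 220,
    "unconfirmed": 117 / 220,
}

#: mean fibre CSA per innervation class, µm² (reference study group means)
DEFAULT_CLASS_CSA_UM2 = {
    "graft": 922.3,
    "endogenous": 1018.3,
    "denervated": 525.4,
    "unconfirmed": 668.8,
}

MUSCLE_CHANNEL_ROLES = {"fiber": 0, "btx": 1, "gfp": 2, "chat": 3}
NERVE_CHANNEL_ROLES = {"bIII": 0, "chat": 1}


class PackingError(RuntimeError):
    """Raised when the requested objects cannot be packed without overlap."""

    def __init__(self, requested: int, achieved: int, kind: str):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not pack {requested} {kind}; achievable count under these settings: {achieved}"
        )


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with given arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


# ---------------------------------------------------------------------------
# muscle phantom
# ---------------------------------------------------------------------------


@dataclass
class MusclePhantomSpec:
    """Parameters of the longitudinal-section muscle phantom.

    Defaults reproduce the reference study conditions: 30-µm section,
    class proportions and per-class mean CSAs of the quantified muscle,
    moderately flattened fibres so that typical fibres fit the section
    thickness without clipping.
    """

    n_fibers: int = 20
    class_fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    csa_mean_um2: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_CSA_UM2))
    csa_cv: float = 0.25
    fiber_eccentricity_range: tuple[float, float] = (0.6, 0.85)
    axis_tilt_deg: float = 5.0
    voxel_size_um: tuple[float, float, float] = (1.0, 0.5, 0.5)  # (x, y, z)
    section_thickness_um: float = 30.0
    fiber_length_um: float = 40.0
    endplate_radius_um: float = 4.0
    axon_radius_um: float = 1.5
    psf_sigma_um: float = 0.4
    poisson_scale: float = 100.0  # photons per intensity unit; 0 disables
    gaussian_sd: float = 0.01
    fiber_gap_um: float = 4.0
    lateral_extent_um: float | None = None  # None: pack fibres in a row and size the volume
    seed: int = 0

    def validate(self) -> None:
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if set(self.class_fractions) != set(CLASS_NAMES):
            raise ValueError(f"class_fractions must have keys {CLASS_NAMES}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        for name, m in self.csa_mean_um2.items():
            if m <= 0:
                raise ValueError(f"csa_mean_um2[{name!r}] must be > 0")
        lo, hi = self.fiber_eccentricity_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("fiber_eccentricity_range must satisfy 0 <= lo <= hi < 1")
        for v in (
            *self.voxel_size_um,
            self.section_thickness_um,
            self.fiber_length_um,
            self.endplate_radius_um,
            self.axon_radius_um,
        ):
            if v <= 0:
                raise ValueError("all scale parameters must be > 0")
        if self.csa_cv < 0 or self.psf_sigma_um < 0 or self.gaussian_sd < 0:
            raise ValueError("csa_cv, psf_sigma_um, gaussian_sd must be >= 0")
        if self.axis_tilt_deg < 0 or self.axis_tilt_deg >= 90:
            raise ValueError("axis_tilt_deg must be in [0, 90)")


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a muscle phantom.

    ``fibers`` has one row per fibre (fiber_id, csa_um2 = π·a·b,
    innervation_class, axis direction, in-section centre, semi-axes,
    clipped flag, endplate ids); ``endplates`` one row per drawn endplate;
    ``label_volume`` is the (z, y, x) int32 fibre-label raster.
    """

    fibers: pd.DataFrame
    endplates: pd.DataFrame
    label_volume: np.ndarray


def sample_fiber_population(spec: MusclePhantomSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the per-fibre class labels and true CSAs (no rasterisation).

    Classes are multinomial draws from ``class_fractions``; CSA is lognormal
    with the class mean and shared CV. This is the statistical core of the
    muscle phantom and is also used directly for parameter-recovery studies.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    probs = np.array([spec.class_fractions[c] for c in CLASS_NAMES])
    classes = rng.choice(len(CLASS_NAMES), size=spec.n_fibers, p=probs)
    csa = np.empty(spec.n_fibers)
    for ci, cname in enumerate(CLASS_NAMES):
        mask = classes == ci
        if spec.csa_cv == 0:
            csa[mask] = spec.csa_mean_um2[cname]
        else:
            mu, sigma = _lognormal_params(spec.csa_mean_um2[cname], spec.csa_cv)
            csa[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
    return pd.DataFrame(
        {
            "fiber_id": np.arange(1, spec.n_fibers + 1),
            "innervation_class": [CLASS_NAMES[c] for c in classes],
            "csa_um2": csa,
        }
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _fiber_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane orthonormal basis (u ~ y, v ~ z) perpendicular to the axis."""
    y_hat = np.array([0.0, 1.0, 0.0])
    u = _unit(y_hat - np.dot(y_hat, axis) * axis)
    v = np.cross(axis, u)
    return u, v


def _rasterize_ellipse_cylinder(
    target: np.ndarray,
    labels: np.ndarray,
    label: int,
    center: np.ndarray,
    axis: np.ndarray,
    a_um: float,
    b_um: float,
    voxel: tuple[float, float, float],
) -> None:
    """Paint an elliptical cylinder (infinite along its axis, clipped by the
    volume) into ``target`` (float, set to 1) and ``labels``."""
    vx, vy, vz = voxel
    nz, ny, nx = target.shape
    u, v = _fiber_frame(axis)
    # conservative bounding box in y and z around the swept cylinder
    x_extent = (nx - 1) * vx
    slope_y = abs(axis[1] / axis[0])
    slope_z = abs(axis[2] / axis[0])
    half_y = a_um + slope_y * x_extent / 2 + vy
    half_z = b_um + slope_z * x_extent / 2 + vz
    j0 = max(0, int(np.floor((center[1] - half_y) / vy)))
    j1 = min(ny, int(np.ceil((center[1] + half_y) / vy)) + 1)
    k0 = max(0, int(np.floor((center[2] - half_z) / vz)))
    k1 = min(nz, int(np.ceil((center[2] + half_z) / vz)) + 1)
    if j0 >= j1 or k0 >= k1:
        return
    zc, yc, xc = np.meshgrid(
        np.arange(k0, k1) * vz,
        np.arange(j0, j1) * vy,
        np.arange(nx) * vx,
        indexing="ij",
    )
    px = xc - center[0]
    py = yc - center[1]
    pz = zc - center[2]
    t = px * axis[0] + py * axis[1] + pz * axis[2]
    ru = px * u[0] + py * u[1] + pz * u[2]
    rv = px * v[0] + py * v[1] + pz * v[2]
    inside = (ru / a_um) ** 2 + (rv / b_um) ** 2 <= 1.0
    sub = target[k0:k1, j0:j1, :]
    sub[inside] = 1.0
    lsub = labels[k0:k1, j0:j1, :]
    lsub[inside] = label


def _rasterize_ball(target: np.ndarray, center: np.ndarray, radius: float, voxel) -> None:
    vx, vy, vz = voxel
    nz, ny, nx = target.shape
    i0 = max(0, int(np.floor((center[0] - radius) / vx)))
    i1 = min(nx, int(np.ceil((center[0] + radius) / vx)) + 1)
    j0 = max(0, int(np.floor((center[1] - radius) / vy)))
    j1 = min(ny, int(np.ceil((center[1] + radius) / vy)) + 1)
    k0 = max(0, int(np.floor((center[2] - radius) / vz)))
    k1 = min(nz, int(np.ceil((center[2] + radius) / vz)) + 1)
    if i0 >= i1 or j0 >= j1 or k0 >= k1:
        return
    zc, yc, xc = np.meshgrid(
        np.arange(k0, k1) * vz, np.arange(j0, j1) * vy, np.arange(i0, i1) * vx, indexing="ij"
    )
    inside = (xc - center[0]) ** 2 + (yc - center[1]) ** 2 + (zc - center[2]) ** 2 <= radius**2
    sub = target[k0:k1, j0:j1, i0:i1]
    sub[inside] = 1.0


def _rasterize_tube_x(target: np.ndarray, center: np.ndarray, radius: float, half_len: float, voxel) -> None:
    """A thin cylinder along x through ``center`` (an axon segment)."""
    vx, vy, vz = voxel
    nz, ny, nx = target.shape
    i0 = max(0, int(np.floor((center[0] - half_len) / vx)))
    i1 = min(nx, int(np.ceil((center[0] + half_len) / vx)) + 1)
    j0 = max(0, int(np.floor((center[1] - radius) / vy)))
    j1 = min(ny, int(np.ceil((center[1] + radius) / vy)) + 1)
    k0 = max(0, int(np.floor((center[2] - radius) / vz)))
    k1 = min(nz, int(np.ceil((center[2] + radius) / vz)) + 1)
    if i0 >= i1 or j0 >= j1 or k0 >= k1:
        return
    zc, yc = np.meshgrid(np.arange(k0, k1) * vz, np.arange(j0, j1) * vy, indexing="ij")
    inside = (yc - center[1]) ** 2 + (zc - center[2]) ** 2 <= radius**2
    sub = target[k0:k1, j0:j1, i0:i1]
    sub[inside, :] = 1.0


def generate_muscle_phantom(spec: MusclePhantomSpec) -> tuple[VolumeImage, PhantomTruth]:
    """Generate a calibrated 4-channel muscle volume and its ground truth.

    Fibres are straight elliptical cylinders spanning the volume along x,
    individually tilted by up to ``axis_tilt_deg``; true CSA is the analytic
    ellipse area π·a·b perpendicular to each fibre's own axis. Graft- and
    endogenous-class fibres carry an endplate blob overlapped by a GFP⁺ or
    ChAT⁺ (GFP⁻) terminal respectively; denervated fibres a bare endplate;
    unconfirmed fibres none (their endplate lies outside the volume).
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    pop_seq, geom_seq, noise_seq = ss.spawn(3)
    pop = sample_fiber_population(spec, np.random.default_rng(pop_seq))
    geom_rng = np.random.default_rng(geom_seq)
    noise_rng = np.random.default_rng(noise_seq)

    vx, vy, vz = spec.voxel_size_um
    thickness = spec.section_thickness_um
    length = spec.fiber_length_um
    max_tilt = np.deg2rad(spec.axis_tilt_deg)

    # per-fibre geometry: eccentricity -> semi-axes, tilt axis, z centre
    n = spec.n_fibers
    ecc = geom_rng.uniform(*spec.fiber_eccentricity_range, size=n)
    ratio = np.sqrt(1.0 - ecc**2)  # b / a
    a_um = np.sqrt(pop["csa_um2"].to_numpy() / (np.pi * ratio))
    b_um = a_um * ratio
    tilt = geom_rng.uniform(0, max_tilt, size=n)
    azim = geom_rng.uniform(0, 2 * np.pi, size=n)
    axes = np.stack(
        [np.cos(tilt), np.sin(tilt) * np.cos(azim), np.sin(tilt) * np.sin(azim)], axis=1
    )

    margin = 1.0
    z_centers = np.empty(n)
    clipped = np.zeros(n, dtype=bool)
    for i in range(n):
        z_room = thickness - 2 * (b_um[i] + margin)
        if z_room <= 0:
            z_centers[i] = thickness / 2
            clipped[i] = True
        else:
            z_centers[i] = b_um[i] + margin + geom_rng.uniform(0, z_room)

    # lateral placement: packed row (auto extent) or random within a fixed extent
    sweep_y = length * np.abs(axes[:, 1] / axes[:, 0])
    half_y = a_um + sweep_y / 2
    y_centers = np.empty(n)
    if spec.lateral_extent_um is None:
        cursor = spec.fiber_gap_um
        for i in range(n):
            y_centers[i] = cursor + half_y[i]
            cursor += 2 * half_y[i] + spec.fiber_gap_um
        extent_y = cursor
    else:
        extent_y = spec.lateral_extent_um
        placed: list[int] = []
        attempts = 0
        for i in range(n):
            ok = False
            while attempts < 10 * n:
                attempts += 1
                cand = geom_rng.uniform(half_y[i] + margin, extent_y - half_y[i] - margin)
                if all(abs(cand - y_centers[j]) > half_y[i] + half_y[j] + spec.fiber_gap_um for j in placed):
                    y_centers[i] = cand
                    placed.append(i)
                    ok = True
                    break
            if not ok:
                raise PackingError(n, len(placed), "fibres")

    nx = max(2, int(round(length / vx)))
    ny = max(2, int(round(extent_y / vy)))
    nz = max(2, int(round(thickness / vz)))
    channels = np.zeros((4, nz, ny, nx), dtype=np.float32)
    labels = np.zeros((nz, ny, nx), dtype=np.int32)

    fiber_ch = channels[MUSCLE_CHANNEL_ROLES["fiber"]]
    btx_ch = channels[MUSCLE_CHANNEL_ROLES["btx"]]
    gfp_ch = channels[MUSCLE_CHANNEL_ROLES["gfp"]]
    chat_ch = channels[MUSCLE_CHANNEL_ROLES["chat"]]

    ep_rows = []
    ep_ids_per_fiber: list[list[int]] = [[] for _ in range(n)]
    next_ep = 1
    x_mid = (nx - 1) * vx / 2

    for i in range(n):
        center = np.array([x_mid, y_centers[i], z_centers[i]])
        _rasterize_ellipse_cylinder(
            fiber_ch, labels, int(pop["fiber_id"].iloc[i]), center, axes[i], a_um[i], b_um[i], (vx, vy, vz)
        )
        # clipped if the ellipse crosses the z faces of the section
        if z_centers[i] - b_um[i] < 0 or z_centers[i] + b_um[i] > thickness:
            clipped[i] = True

        cls = pop["innervation_class"].iloc[i]
        if cls == "unconfirmed":
            continue
        # endplate on the fibre surface, preferring whichever z side has room
        u, v = _fiber_frame(axes[i])
        x_e = x_mid + geom_rng.uniform(-length / 4, length / 4)
        on_axis = center + ((x_e - center[0]) / axes[i][0]) * axes[i]
        r_ep = spec.endplate_radius_um
        for direction in (v, -v, u, -u):
            c_ep = on_axis + (b_um[i] if abs(direction[2]) > 0.5 else a_um[i]) * direction
            if r_ep <= c_ep[2] <= thickness - r_ep and r_ep <= c_ep[1] <= extent_y - r_ep:
                break
        _rasterize_ball(btx_ch, c_ep, r_ep, (vx, vy, vz))
        if cls == "graft":
            _rasterize_ball(gfp_ch, c_ep, 0.9 * r_ep, (vx, vy, vz))
            _rasterize_tube_x(gfp_ch, c_ep, spec.axon_radius_um, 12.0, (vx, vy, vz))
            _rasterize_ball(chat_ch, c_ep, 0.9 * r_ep, (vx, vy, vz))
            _rasterize_tube_x(chat_ch, c_ep, spec.axon_radius_um, 12.0, (vx, vy, vz))
            cat = "graft_full"
        elif cls == "endogenous":
            _rasterize_ball(chat_ch, c_ep, 0.9 * r_ep, (vx, vy, vz))
            _rasterize_tube_x(chat_ch, c_ep, spec.axon_radius_um, 12.0, (vx, vy, vz))
            cat = "endogenous"
        else:
            cat = "denervated"
        ep_rows.append(
            {
                "endplate_id": next_ep,
                "fiber_id": int(pop["fiber_id"].iloc[i]),
                "x_um": c_ep[0],
                "y_um": c_ep[1],
                "z_um": c_ep[2],
                "category": cat,
            }
        )
        ep_ids_per_fiber[i].append(next_ep)
        next_ep += 1

    if spec.psf_sigma_um > 0:
        sig = (spec.psf_sigma_um / vz, spec.psf_sigma_um / vy, spec.psf_sigma_um / vx)
        for c in range(4):
            ndi.gaussian_filter(channels[c], sigma=sig, output=channels[c])
    if spec.poisson_scale > 0:
        channels = (
            noise_rng.poisson(np.clip(channels, 0, None) * spec.poisson_scale) / spec.poisson_scale
        ).astype(np.float32)
    if spec.gaussian_sd > 0:
        channels = channels + noise_rng.normal(0, spec.gaussian_sd, size=channels.shape).astype(np.float32)
        channels = np.clip(channels, 0, None)

    fibers = pop.copy()
    fibers["axis_x"] = axes[:, 0]
    fibers["axis_y"] = axes[:, 1]
    fibers["axis_z"] = axes[:, 2]
    fibers["centroid_y_um"] = y_centers
    fibers["centroid_z_um"] = z_centers
    fibers["a_um"] = a_um
    fibers["b_um"] = b_um
    fibers["clipped"] = clipped
    fibers["endplate_ids"] = [";".join(map(str, ids)) for ids in ep_ids_per_fiber]

    ep_cols = ["endplate_id", "fiber_id", "x_um", "y_um", "z_um", "category"]
    endplates = pd.DataFrame(ep_rows, columns=ep_cols)

    vol = VolumeImage(
        data=channels, voxel_size_um=spec.voxel_size_um, channel_roles=dict(MUSCLE_CHANNEL_ROLES)
    )
    return vol, PhantomTruth(fibers=fibers, endplates=endplates, label_volume=labels)


def generate_cylinder_volume(
    radius_um: float = 8.0,
    axis=(1.0, 0.0, 0.0),
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 0.5),
    shape_zyx: tuple[int, int, int] = (64, 64, 48),
) -> VolumeImage:
    """A noise-free circular cylinder along ``axis``, centred in the volume.

    The simplest analytic phantom: any plane perpendicular to the axis cuts
    a disc of area exactly π r²; a plane tilted by θ cuts an ellipse of
    area π r² / cos θ. Used to validate reslicing geometry.
    """
    vx, vy, vz = voxel_size_um
    nz, ny, nx = shape_zyx
    d = np.asarray(axis, dtype=float)
    d = d / np.linalg.norm(d)
    zc, yc, xc = np.meshgrid(
        np.arange(nz) * vz, np.arange(ny) * vy, np.arange(nx) * vx, indexing="ij"
    )
    center = np.array([(nx - 1) * vx / 2, (ny - 1) * vy / 2, (nz - 1) * vz / 2])
    px, py, pz = xc - center[0], yc - center[1], zc - center[2]
    t = px * d[0] + py * d[1] + pz * d[2]
    r2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
    data = (r2 <= radius_um**2).astype(np.float32)[np.newaxis]
    return VolumeImage(data, voxel_size_um, {"fiber": 0})


# ---------------------------------------------------------------------------
# nerve phantom
# ---------------------------------------------------------------------------


@dataclass
class NervePhantomSpec:
    """Parameters of the packed-disc nerve cross-section phantom.

    The calibre distribution is a lognormal mixture on axon CSA (µm²),
    bimodal by default (small unmyelinated-ish and large motor-ish modes);
    a ``motor_fraction`` subset is additionally ChAT⁺.
    """

    n_axons: int = 300
    motor_fraction: float = 0.35
    calibre_means_um2: tuple[float, ...] = (3.0, 20.0)
    calibre_cvs: tuple[float, ...] = (0.6, 0.4)
    calibre_weights: tuple[float, ...] = (0.65, 0.35)
    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.2
    min_gap_um: float = 0.3
    psf_sigma_um: float = 0.2
    poisson_scale: float = 100.0
    gaussian_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_axons < 0:
            raise ValueError("n_axons must be >= 0")
        if not 0 <= self.motor_fraction <= 1:
            raise ValueError("motor_fraction must be in [0, 1]")
        if not len(self.calibre_means_um2) == len(self.calibre_cvs) == len(self.calibre_weights):
            raise ValueError("mixture components must have equal-length means/cvs/weights")
        if abs(sum(self.calibre_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(m <= 0 for m in self.calibre_means_um2) or any(c < 0 for c in self.calibre_cvs):
            raise ValueError("mixture means must be > 0 and cvs >= 0")
        if self.pixel_size_um <= 0 or self.min_gap_um < 0:
            raise ValueError("pixel_size_um must be > 0 and min_gap_um >= 0")


def sample_axon_calibres(spec: NervePhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw axon CSAs (µm²) from the lognormal mixture."""
    comp = rng.choice(len(spec.calibre_weights), size=spec.n_axons, p=np.asarray(spec.calibre_weights))
    csa = np.empty(spec.n_axons)
    for k, (m, cv) in enumerate(zip(spec.calibre_means_um2, spec.calibre_cvs)):
        mask = comp == k
        if cv == 0:
            csa[mask] = m
        else:
            mu, sigma = _lognormal_params(m, cv)
            csa[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
    return csa


def generate_nerve_phantom(spec: NervePhantomSpec) -> tuple[VolumeImage, pd.DataFrame]:
    """Generate a 2-channel nerve section and its truth axon table.

    Returns a single-z-plane :class:`VolumeImage` (channels βIII-tubulin and
    ChAT) and a table with one row per axon: ``axon_id``, analytic
    ``csa_um2`` (π·r²), ``is_motor``, centre coordinates in µm.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    draw_rng, place_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    h_px, w_px = spec.image_size_px
    px = spec.pixel_size_um
    height, width = h_px * px, w_px * px
    cols = ["axon_id", "csa_um2", "is_motor", "x_um", "y_um"]

    if spec.n_axons == 0:
        data = np.zeros((2, 1, h_px, w_px), dtype=np.float32)
        vol = VolumeImage(data, (px, px, 1.0), dict(NERVE_CHANNEL_ROLES))
        return vol, pd.DataFrame(columns=cols)

    csa = sample_axon_calibres(spec, draw_rng)
    radii = np.sqrt(csa / np.pi)
    is_motor = draw_rng.random(spec.n_axons) < spec.motor_fraction
    # pack large axons first (greedy random sequential adsorption)
    order = np.argsort(-radii)
    centers = np.full((spec.n_axons, 2), np.nan)
    placed: list[int] = []
    attempts = 0
    max_attempts = 10 * spec.n_axons
    for i in order:
        r = radii[i]
        ok = False
        while attempts < max_attempts:
            attempts += 1
            cx = place_rng.uniform(r, width - r)
            cy = place_rng.uniform(r, height - r)
            if all(
                (cx - centers[j, 0]) ** 2 + (cy - centers[j, 1]) ** 2
                > (r + radii[j] + spec.min_gap_um) ** 2
                for j in placed
            ):
                centers[i] = (cx, cy)
                placed.append(i)
                ok = True
                break
        if not ok:
            raise PackingError(spec.n_axons, len(placed), "axons")

    yy, xx = np.meshgrid(np.arange(h_px) * px, np.arange(w_px) * px, indexing="ij")
    total = np.zeros((h_px, w_px), dtype=np.float32)
    motor = np.zeros((h_px, w_px), dtype=np.float32)
    for i in range(spec.n_axons):
        cx, cy = centers[i]
        r = radii[i]
        j0 = max(0, int((cy - r) / px) - 1)
        j1 = min(h_px, int((cy + r) / px) + 2)
        i0 = max(0, int((cx - r) / px) - 1)
        i1 = min(w_px, int((cx + r) / px) + 2)
        disc = (xx[j0:j1, i0:i1] - cx) ** 2 + (yy[j0:j1, i0:i1] - cy) ** 2 <= r**2
        total[j0:j1, i0:i1][disc] = 1.0
        if is_motor[i]:
            motor[j0:j1, i0:i1][disc] = 1.0

    data = np.stack([total, motor])[:, np.newaxis]  # (c, z=1, y, x)
    if spec.psf_sigma_um > 0:
        s = spec.psf_sigma_um / px
        for c in range(2):
            ndi.gaussian_filter(data[c, 0], sigma=s, output=data[c, 0])
    if spec.poisson_scale > 0:
        data = (noise_rng.poisson(np.clip(data, 0, None) * spec.poisson_scale) / spec.poisson_scale).astype(
            np.float32
        )
    if spec.gaussian_sd > 0:
        data = np.clip(data + noise_rng.normal(0, spec.gaussian_sd, data.shape).astype(np.float32), 0, None)

    table = pd.DataFrame(
        {
            "axon_id": np.arange(1, spec.n_axons + 1),
            "csa_um2": csa,
            "is_motor": is_motor,
            "x_um": centers[:, 0],
            "y_um": centers[:, 1],
        }
    )
    vol = VolumeImage(data, (px, px, 1.0), dict(NERVE_CHANNEL_ROLES))
    return vol, table


# ---------------------------------------------------------------------------
# force traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimEvent:
    """One stimulation epoch: a pulse train (or single pulse if frequency 0)."""

    t_start_s: float
    t_end_s: float
    kind: str = "ONS"  # optical vs electrical nerve stimulation
    frequency_hz: float = 0.0
    intensity: float = 1.0


StimProgram = Sequence[StimEvent]


@dataclass
class ForceTrace:
    """A uniformly sampled force-vs-time recording with stimulus annotations."""

    time_s: np.ndarray
    force_g: np.ndarray
    sampling_hz: float
    stim_events: list[StimEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_g = np.asarray(self.force_g, dtype=float)
        if self.time_s.shape != self.force_g.shape:
            raise ValueError("time_s and force_g must have equal length")
        if len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("sampling must be uniform")
        for ev in self.stim_events:
            if ev.t_start_s < self.time_s[0] - 1e-9 or ev.t_end_s > self.time_s[-1] + 1e-9:
                raise ValueError(f"stimulus event {ev} outside trace time range")


@dataclass
class TracePhantomSpec:
    """Motor-unit pool driving the synthetic force traces.

    Defaults model a partially reinnervated muscle with 6 recruitable units.
    ``tetanic_fusion_gain`` scales twitches inside ≥20 Hz trains so that the
    fused tetanic plateau exceeds linear twitch summation (defaults give a
    tetanus:twitch ratio ≈ 5 and a maximal fused force ≈ 7.5 g).
    """

    n_motor_units: int = 6
    unit_twitch_forces_g: tuple[float, ...] = (0.12, 0.18, 0.22, 0.28, 0.32, 0.38)
    recruitment_thresholds: tuple[float, ...] = (0.1, 0.25, 0.4, 0.55, 0.7, 0.85)
    tetanic_fusion_gain: float = 3.0
    fatigue_tau_s: float = np.inf
    twitch_time_ms: float = 25.0
    sampling_hz: float = 1000.0
    noise_sd_g: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n_motor_units != len(self.unit_twitch_forces_g) or self.n_motor_units != len(
            self.recruitment_thresholds
        ):
            raise ValueError("unit forces and thresholds must match n_motor_units")
        if any(f <= 0 for f in self.unit_twitch_forces_g):
            raise ValueError("unit twitch forces must be > 0")
        thr = np.asarray(self.recruitment_thresholds)
        if len(thr) > 1 and not np.all(np.diff(thr) > 0):
            raise ValueError("recruitment thresholds must be strictly increasing")
        if self.tetanic_fusion_gain < 1:
            raise ValueError("tetanic_fusion_gain must be >= 1")
        if self.fatigue_tau_s <= 0:
            raise ValueError("fatigue_tau_s must be > 0 (np.inf disables fatigue)")
        if self.sampling_hz <= 0 or self.twitch_time_ms <= 0 or self.noise_sd_g < 0:
            raise ValueError("sampling_hz, twitch_time_ms > 0; noise_sd_g >= 0")


def twitch_kernel(spec: TracePhantomSpec) -> np.ndarray:
    """Peak-normalised alpha-function twitch, sampled at the trace rate."""
    tau = spec.twitch_time_ms / 1000.0
    t = np.arange(0, 8 * tau, 1.0 / spec.sampling_hz)
    return (t / tau) * np.exp(1.0 - t / tau)


def ramp_program(
    intensities: Sequence[float], spacing_s: float = 0.5, t_first_s: float = 0.5, kind: str = "ONS"
) -> list[StimEvent]:
    """Single twitch pulses at monotonically increasing stimulus intensities."""
    return [
        StimEvent(t_first_s + i * spacing_s, t_first_s + i * spacing_s, kind, 0.0, float(inten))
        for i, inten in enumerate(intensities)
    ]


def tetanus_program(
    duration_s: float = 1.0, t_start_s: float = 0.5, frequency_hz: float = 20.0, intensity: float = 1.0, kind: str = "ONS"
) -> list[StimEvent]:
    """One supramaximal tetanic train."""
    return [StimEvent(t_start_s, t_start_s + duration_s, kind, frequency_hz, intensity)]


def fatigue_program(
    n_bursts: int = 180,
    burst_s: float = 0.25,
    period_s: float = 1.0,
    frequency_hz: float = 20.0,
    t_first_s: float = 0.5,
    intensity: float = 1.0,
    kind: str = "ONS",
) -> list[StimEvent]:
    """Repeated-burst fatigue protocol: 250 ms 20 Hz bursts every 1 s, 180 s."""
    return [
        StimEvent(t_first_s + i * period_s, t_first_s + i * period_s + burst_s, kind, frequency_hz, intensity)
        for i in range(n_bursts)
    ]


def generate_force_trace(
    spec: TracePhantomSpec,
    stim_program: StimProgram,
    duration_s: float | None = None,
    fusion_threshold_hz: float = 20.0,
) -> ForceTrace:
    """Synthesize a force trace from the motor-unit pool and a stim program.

    Each pulse recruits every unit whose threshold is at or below the event
    intensity and adds their twitch kernels; pulses inside trains at
    ``fusion_threshold_hz`` or above are scaled by the tetanic fusion gain;
    the whole drive decays as exp(-t/fatigue_tau) from the first stimulus.
    """
    spec.validate()
    events = list(stim_program)
    if not events:
        raise ValueError("stim_program must contain at least one event")
    t_end = max(ev.t_end_s for ev in events)
    if duration_s is None:
        duration_s = t_end + 0.5
    if t_end > duration_s:
        raise ValueError("stimulus program extends beyond trace duration")

    n = int(round(duration_s * spec.sampling_hz)) + 1
    time = np.arange(n) / spec.sampling_hz
    force = np.zeros(n)
    kern = twitch_kernel(spec)
    forces = np.asarray(spec.unit_twitch_forces_g)
    thresholds = np.asarray(spec.recruitment_thresholds)
    t0 = min(ev.t_start_s for ev in events)

    for ev in events:
        recruited = float(forces[thresholds <= ev.intensity + 1e-12].sum())
        if recruited == 0:
            continue
        gain = spec.tetanic_fusion_gain if ev.frequency_hz >= fusion_threshold_hz else 1.0
        if ev.frequency_hz > 0:
            pulse_times = np.arange(ev.t_start_s, ev.t_end_s + 1e-9, 1.0 / ev.frequency_hz)
        else:
            pulse_times = np.array([ev.t_start_s])
        for tp in pulse_times:
            fatigue = np.exp(-(tp - t0) / spec.fatigue_tau_s) if np.isfinite(spec.fatigue_tau_s) else 1.0
            i0 = int(round(tp * spec.sampling_hz))
            seg = min(len(kern), n - i0)
            if seg > 0:
                force[i0 : i0 + seg] += recruited * gain * fatigue * kern[:seg]

    if spec.noise_sd_g > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
        force = force + rng.normal(0, spec.noise_sd_g, size=n)
    return ForceTrace(time, force, spec.sampling_hz, events)


def write_trace(trace: ForceTrace, path) -> None:
    """Write a force trace as CSV (columns time_s, force_g)."""
    pd.DataFrame({"time_s": trace.time_s, "force_g": trace.force_g}).to_csv(path, index=False)


def read_trace(path, stim_events: Sequence[StimEvent] = ()) -> ForceTrace:
    """Read a time/force CSV back into a :class:`ForceTrace`."""
    frame = pd.read_csv(path)
    t = frame["time_s"].to_numpy()
    dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
    return ForceTrace(t, frame["force_g"].to_numpy(), 1.0 / dt, list(stim_events))


def write_events(events: Sequence[StimEvent], path) -> None:
    pd.DataFrame([dataclasses.asdict(ev) for ev in events]).to_csv(path, index=False)


def read_events(path) -> list[StimEvent]:
    frame = pd.read_csv(path)
    return [
        StimEvent(r.t_start_s, r.t_end_s, r.kind, r.frequency_hz, r.intensity)
        for r in frame.itertuples()
    ]
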