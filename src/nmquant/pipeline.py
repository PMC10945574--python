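"""End-to-end digital cross-sectional-area analysis of a longitudinal
muscle volume (the dCALMS workflow).

Steps: estimate the fibre axis (structure tensor, or take a supplied
axis), extract a virtual plane transverse to it, segment fibres and
measure CSA on that plane, detect and classify endplates in the full 3-D
volume, attach each endplate to the fibre region containing its in-plane
projection, and summarize CSA by innervation class.

The canonical CSA is measured on the plane perpendicular to the local
fibre axis; a ``cos_correction`` fallback instead multiplies in-section
area by cos(tilt) for comparison with section-plane measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fiber_csa, innervation, reslice
from .imaging_io import VolumeImage


@dataclass
class DcalmsResult:
    """Everything the muscle-volume analysis produced."""

    plane: reslice.ReslicePlane
    plane_image: reslice.PlaneImage
    segmentation: fiber_csa.SegmentationResult
    fibers: list[fiber_csa.FiberRecord]
    endplates: list[innervation.EndplateRecord]
    summary: pd.DataFrame
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    @property
    def fiber_table(self) -> pd.DataFrame:
        rows = [
            {
                "fiber_id": r.fiber_id,
                "csa_um2": r.csa_um2,
                "centroid_row_um": r.centroid_um[0],
                "centroid_col_um": r.centroid_um[1],
                "plane_id": r.plane_id,
                "innervation_class": r.innervation_class,
                "clipped": r.clipped,
            }
            for r in self.fibers
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "fiber_id",
                "csa_um2",
                "centroid_row_um",
                "centroid_col_um",
                "plane_id",
                "innervation_class",
                "clipped",
            ],
        )


def _project_to_plane(point_um: np.ndarray, plane: reslice.ReslicePlane) -> tuple[float, float]:
    """In-plane (v, u) coordinates of a world point, µm from the image centre."""
    rel = np.asarray(point_um, float) - plane.origin_um
    return float(np.dot(rel, plane.basis_v)), float(np.dot(rel, plane.basis_u))


def attach_endplates_to_plane_labels(
    endplates: list[innervation.EndplateRecord],
    segmentation: fiber_csa.SegmentationResult,
    plane: reslice.ReslicePlane,
    search_radius_um: float = 8.0,
) -> dict[int, str]:
    """Map plane-segmentation labels to innervation classes via endplates.

    Each endplate's centroid is projected along the fibre axis onto the
    transverse plane; the fibre region at (or nearest to, within
    ``search_radius_um``) the projection inherits the endplate's class with
    the usual precedence. Regions without any endplate stay unconfirmed.
    """
    labels = segmentation.labels
    nh, nw = labels.shape
    px = plane.pixel_size_um
    classes: dict[int, set[str]] = {}
    for rec in endplates:
        if rec.category is None:
            continue
        sv, su = _project_to_plane(np.asarray(rec.centroid_um), plane)
        r = sv / px + (nh - 1) / 2
        c = su / px + (nw - 1) / 2
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < nh and 0 <= ci < nw):
            continue
        lab = int(labels[ri, ci])
        if lab == 0:
            rad = max(1, int(round(search_radius_um / px)))
            sub = labels[max(0, ri - rad) : ri + rad + 1, max(0, ci - rad) : ci + rad + 1]
            nz = np.argwhere(sub != 0)
            if nz.size:
                center = np.array([ri - max(0, ri - rad), ci - max(0, ci - rad)])
                d2 = ((nz - center) ** 2).sum(axis=1)
                if d2.min() <= rad**2:
                    lab = int(sub[tuple(nz[np.argmin(d2)])])
        if lab:
            rec.fiber_id = lab
            classes.setdefault(lab, set()).add(innervation.CATEGORY_TO_CLASS[rec.category])
    out: dict[int, str] = {}
    for lab, cset in classes.items():
        for cls in innervation.CLASS_PRECEDENCE:
            if cls in cset:
                out[lab] = cls
                break
    return out


def match_measured_to_truth(
    result: "DcalmsResult",
    truth,
    voxel_size_um: tuple[float, float, float],
) -> pd.DataFrame:
    """Pair measured fibre records with phantom ground truth.

    The truth label volume is resliced (nearest-neighbour) onto the
    analysis plane; each measured region is matched to the truth fibre
    whose label dominates it. Returns one row per matched fibre with
    measured and analytic CSA, both class labels and both clipped flags.
    """
    lab_plane = reslice.reslice_labels(truth.label_volume, voxel_size_um, result.plane)
    truth_by_id = truth.fibers.set_index("fiber_id")
    rows = []
    for rec in result.fibers:
        mask = result.segmentation.labels == rec.fiber_id
        vals, counts = np.unique(lab_plane[mask], return_counts=True)
        tid = int(vals[np.argmax(counts)])
        if tid == 0:
            continue
        row = truth_by_id.loc[tid]
        rows.append(
            {
                "measured_id": rec.fiber_id,
                "truth_id": tid,
                "csa_um2": rec.csa_um2,
                "true_csa_um2": float(row.csa_um2),
                "measured_class": rec.innervation_class,
                "true_class": row.innervation_class,
                "measured_clipped": rec.clipped,
                "true_clipped": bool(row.clipped),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "measured_id",
            "truth_id",
            "csa_um2",
            "true_csa_um2",
            "measured_class",
            "true_class",
            "measured_clipped",
            "true_clipped",
        ],
    )


def analyze_muscle_volume(
    vol: VolumeImage,
    axis: np.ndarray | None = None,
    plane_x_um: float | None = None,
    pixel_size_um: float | None = None,
    seeds: list[tuple[int, int]] | None = None,
    cos_correction: bool = False,
    detect_endplates: bool = True,
    segment_kwargs: dict | None = None,
    endplate_kwargs: dict | None = None,
) -> DcalmsResult:
    """Run the digital-reslicing CSA/innervation analysis on one volume.

    ``axis=None`` estimates the dominant fibre axis from the whole volume.
    With ``cos_correction=True`` the plane is the fixed section-transverse
    plane (normal +x) and each CSA is multiplied by cos(tilt) of the global
    axis instead — the comparison mode for section-plane measurements.
    """
    if axis is None:
        axis = reslice.estimate_fiber_axis(vol)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)

    if cos_correction:
        plane_normal = np.array([1.0, 0.0, 0.0])
        cos_tilt = float(abs(axis[0]))
    else:
        plane_normal = axis
        cos_tilt = 1.0

    plane = reslice.transverse_plane_through(vol, plane_normal, x_um=plane_x_um, pixel_size_um=pixel_size_um)
    plane_image = reslice.reslice_volume(vol, plane)
    seg = fiber_csa.segment_fibers(plane_image, seeds=seeds, **(segment_kwargs or {}))
    fibers = fiber_csa.compute_csa(seg, plane.pixel_size_um)
    if cos_correction:
        for rec in fibers:
            rec.csa_um2 *= cos_tilt

    endplate_records: list[innervation.EndplateRecord] = []
    if detect_endplates and "btx" in vol.channel_roles:
        endplate_records = innervation.detect_endplates(vol, **(endplate_kwargs or {}))
        label_classes = attach_endplates_to_plane_labels(endplate_records, seg, plane)
        for rec in fibers:
            rec.innervation_class = label_classes.get(rec.fiber_id, "unconfirmed")

    summary = fiber_csa.summarize_csa_by_class(fibers)
    return DcalmsResult(
        plane=plane,
        plane_image=plane_image,
        segmentation=seg,
        fibers=fibers,
        endplates=endplate_records,
        summary=summary,
        axis=axis,
    )
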