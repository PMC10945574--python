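"""Endplate detection, colocalization classification and fibre assignment."""

import numpy as np
import pytest

from nmquant import innervation, pipeline
from nmquant import synthetic_data as sd
from nmquant.imaging_io import VolumeImage


@pytest.fixture(scope="module")
def endplate_phantom():
    spec = sd.MusclePhantomSpec(
        n_fibers=12, psf_sigma_um=0.0, poisson_scale=0.0, gaussian_sd=0.0, seed=23
    )
    return spec, *sd.generate_muscle_phantom(spec)


class TestDetection:
    def test_all_truth_endplates_detected_with_accurate_centroids(self, endplate_phantom):
        spec, vol, truth = endplate_phantom
        records = innervation.detect_endplates(vol)
        assert len(records) == len(truth.endplates)
        vx, vy, vz = vol.voxel_size_um
        tol = np.linalg.norm([vx, vy, vz])  # one voxel diagonal
        truth_pts = truth.endplates[["x_um", "y_um", "z_um"]].to_numpy()
        for rec in records:
            d = np.linalg.norm(truth_pts - np.asarray(rec.centroid_um), axis=1)
            assert d.min() <= tol

    def test_blank_btx_channel_gives_empty_list(self):
        vol = VolumeImage(np.zeros((2, 8, 8, 8)), (1, 1, 1), {"fiber": 0, "btx": 1})
        assert innervation.detect_endplates(vol) == []

    def test_endplates_closer_than_blur_merge_into_one(self):
        """Two endplates inside one blur scale become a single component —
        documented resolution limit of the blob detector."""
        data = np.zeros((2, 24, 40, 40), dtype=np.float32)
        vol = VolumeImage(data, (1.0, 1.0, 1.0), {"fiber": 0, "btx": 1})
        zz, yy, xx = np.mgrid[:24, :40, :40].astype(float)
        for cx in (18.0, 23.0):  # centres 5 µm apart, radius 4 µm blobs
            data[1][(xx - cx) ** 2 + (yy - 20) ** 2 + (zz - 12) ** 2 <= 16.0] = 1.0
        records = innervation.detect_endplates(vol, smooth_sigma_um=1.0)
        assert len(records) == 1

    def test_size_bounds_filter_components(self, endplate_phantom):
        spec, vol, truth = endplate_phantom
        none = innervation.detect_endplates(vol, min_volume_um3=1e5)
        assert none == []


class TestClassification:
    @pytest.mark.parametrize(
        "gfp,chat,expected",
        [
            (0.9, 0.0, "graft_full"),
            (0.5, 0.0, "graft_full"),
            (0.2, 0.9, "graft_partial"),
            (0.05, 0.0, "graft_partial"),
            (0.0, 0.7, "endogenous"),
            (0.04, 0.05, "endogenous"),
            (0.0, 0.0, "denervated"),
            (0.04, 0.04, "denervated"),
        ],
    )
    def test_threshold_taxonomy(self, gfp, chat, expected):
        assert innervation.classify_endplate(gfp, chat) == expected

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError, match="t_min"):
            innervation.classify_endplate(0.5, 0.5, t_min=0.6, t_full=0.5)

    def test_category_partition_is_total(self, endplate_phantom):
        """Category counts partition the endplate count."""
        spec, vol, truth = endplate_phantom
        records = innervation.detect_endplates(vol)
        counts = {c: 0 for c in innervation.ENDPLATE_CATEGORIES}
        for r in records:
            counts[r.category] += 1
        assert sum(counts.values()) == len(records)

    def test_raising_t_min_never_increases_graft_count(self, endplate_phantom):
        spec, vol, truth = endplate_phantom
        records = innervation.detect_endplates(vol)

        def graft_count(t_min):
            return sum(
                1
                for r in records
                if innervation.classify_endplate(r, t_min=t_min).startswith("graft")
            )

        counts = [graft_count(t) for t in (0.02, 0.05, 0.2, 0.4)]
        assert counts == sorted(counts, reverse=True)

    def test_classification_accuracy_on_noisy_phantom(self):
        """At SNR 5 (Gaussian sd = 20% of signal, plus shot noise) at least
        95% of endplates keep their true category."""
        total, correct = 0, 0
        for seed in (101, 102, 103):
            spec = sd.MusclePhantomSpec(
                n_fibers=14,
                class_fractions={"graft": 0.3, "endogenous": 0.3, "denervated": 0.3, "unconfirmed": 0.1},
                psf_sigma_um=0.4,
                poisson_scale=100.0,
                gaussian_sd=0.2,
                seed=seed,
            )
            vol, truth = sd.generate_muscle_phantom(spec)
            records = innervation.detect_endplates(vol)
            truth_pts = truth.endplates[["x_um", "y_um", "z_um"]].to_numpy()
            for rec in records:
                d = np.linalg.norm(truth_pts - np.asarray(rec.centroid_um), axis=1)
                j = int(np.argmin(d))
                if d[j] > 5.0:
                    continue
                total += 1
                if truth.endplates.category.iloc[j] == rec.category:
                    correct += 1
        assert total >= 20
        assert correct / total >= 0.95


class TestInnervationFraction:
    def test_reference_counts_give_10_5_percent(self):
        assert innervation.innervation_fraction(364, 3482) == 10.5

    @pytest.mark.parametrize("n_in,n_tot,expected", [(0, 100, 0.0), (100, 100, 100.0)])
    def test_extremes(self, n_in, n_tot, expected):
        assert innervation.innervation_fraction(n_in, n_tot) == expected

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            innervation.innervation_fraction(0, 0)

    def test_more_innervated_than_total_is_error(self):
        with pytest.raises(ValueError):
            innervation.innervation_fraction(5, 3)


class TestAssignFibers:
    def make_volume_with_fiber(self):
        labels = np.zeros((10, 20, 20), dtype=np.int32)
        labels[2:8, 5:15, :] = 1
        return labels

    def ep(self, eid, category, xyz=(10.0, 10.0, 5.0)):
        rec = innervation.EndplateRecord(eid, xyz, 50.0, 0.0, 0.0)
        rec.category = category
        return rec

    def test_single_graft_endplate_gives_graft_fiber(self):
        labels = self.make_volume_with_fiber()
        out = innervation.assign_fibers(labels, (1, 1, 1), [self.ep(1, "graft_full")])
        assert out == {1: "graft"}

    def test_graft_beats_denervated_on_same_fiber(self):
        """A fibre carrying both a graft-innervated and a denervated
        endplate counts as graft (precedence)."""
        labels = self.make_volume_with_fiber()
        eps = [self.ep(1, "denervated", (4.0, 10.0, 5.0)), self.ep(2, "graft_partial", (15.0, 10.0, 5.0))]
        out = innervation.assign_fibers(labels, (1, 1, 1), eps)
        assert out == {1: "graft"}

    def test_endogenous_beats_denervated(self):
        labels = self.make_volume_with_fiber()
        eps = [self.ep(1, "denervated", (4.0, 10.0, 5.0)), self.ep(2, "endogenous", (15.0, 10.0, 5.0))]
        assert innervation.assign_fibers(labels, (1, 1, 1), eps) == {1: "endogenous"}

    def test_fiber_without_endplate_is_unconfirmed(self):
        labels = self.make_volume_with_fiber()
        labels[2:8, 16:19, :] = 2  # second fibre, no endplate
        out = innervation.assign_fibers(labels, (1, 1, 1), [self.ep(1, "graft_full")])
        assert out[2] == "unconfirmed"

    def test_endplate_near_but_outside_fiber_attaches_within_radius(self):
        labels = self.make_volume_with_fiber()
        out = innervation.assign_fibers(
            labels, (1, 1, 1), [self.ep(1, "graft_full", (10.0, 17.0, 5.0))], search_radius_um=6.0
        )
        assert out == {1: "graft"}

    def test_full_pipeline_recovers_truth_classes(self, endplate_phantom):
        """End-to-end class assignment on a clean phantom matches truth for
        every unclipped fibre."""
        spec, vol, truth = endplate_phantom
        from nmquant import reslice

        res = pipeline.analyze_muscle_volume(vol)
        lab_plane = reslice.reslice_labels(truth.label_volume, vol.voxel_size_um, res.plane)
        truth_cls = dict(zip(truth.fibers.fiber_id, truth.fibers.innervation_class))
        checked = 0
        for rec in res.fibers:
            if rec.clipped:
                continue
            mask = res.segmentation.labels == rec.fiber_id
            vals, counts = np.unique(lab_plane[mask], return_counts=True)
            tid = int(vals[np.argmax(counts)])
            if tid == 0:
                continue
            assert rec.innervation_class == truth_cls[tid]
            checked += 1
        assert checked >= 6
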