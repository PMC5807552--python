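"""3D spot detection, overlap classification, containment, line profiles."""

import numpy as np
import pandas as pd
import pytest

import fluxscreen as fs


def spotset_from_labels(labels, voxel_size=(1.0, 1.0, 1.0)):
    """Build a SpotSet directly from a label image (unit intensities)."""
    labels = np.asarray(labels, dtype=np.int32)
    rows = []
    for lab in np.unique(labels[labels > 0]):
        vox = np.argwhere(labels == lab)
        rows.append(
            {
                "label": int(lab),
                "volume_vox": len(vox),
                "volume_um3": float(len(vox) * np.prod(voxel_size)),
                "mean_intensity": 1.0,
                "cv": 0.0,
                "centroid_z": vox[:, 0].mean(),
                "centroid_y": vox[:, 1].mean(),
                "centroid_x": vox[:, 2].mean(),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["label", "volume_vox", "volume_um3", "mean_intensity", "cv",
                 "centroid_z", "centroid_y", "centroid_x"],
    )
    return fs.SpotSet(labels=labels, table=table, voxel_size_um=voxel_size)


def box_labels(shape, boxes):
    """Label image with axis-aligned boxes: [(label, zsl, ysl, xsl), ...]."""
    labels = np.zeros(shape, dtype=np.int32)
    for lab, zs, ys, xs in boxes:
        labels[zs, ys, xs] = lab
    return labels


class TestDetectSpots:
    def test_blank_stack_gives_empty_spotset(self):
        spots = fs.detect_spots(np.zeros((10, 20, 20)))
        assert len(spots) == 0

    def test_single_spot_centroid_within_one_voxel(self):
        cfg = fs.ImageSimConfig(
            shape=(20, 40, 40), spots_a=[fs.SpotSpec(center=(10, 20, 20), radius=4)]
        )
        stack, truth = fs.simulate_image_stack(cfg)
        spots = fs.detect_spots(stack[0])
        assert len(spots) == 1
        got = spots.table[["centroid_z", "centroid_y", "centroid_x"]].iloc[0].to_numpy()
        assert np.all(np.abs(got - truth[["z", "y", "x"]].iloc[0].to_numpy()) <= 1.0)

    def test_dim_flat_blob_removed_by_intensity_filter(self):
        # low-CV but dim structure: fails mean-intensity filter, while a
        # bright spot in the same stack survives
        vol = np.zeros((16, 48, 48))
        vol[6:10, 6:14, 6:14] = 5.0      # dim flat blob
        vol[6:10, 30:38, 30:38] = 200.0  # bright spot
        kept = fs.detect_spots(vol, threshold=1.0, intensity_min=50.0)
        assert len(kept) == 1
        assert kept.table["mean_intensity"].iloc[0] > 50.0
        both = fs.detect_spots(vol, threshold=1.0, intensity_min=0.0)
        assert len(both) == 2

    def test_cv_filter_drops_heterogeneous_object(self):
        vol = np.zeros((12, 24, 24))
        vol[4:8, 4:10, 4:10] = 100.0               # homogeneous object
        vol[4:8, 14:20, 14:20] = 100.0
        vol[5, 16, 16] = 5000.0                    # spike → much higher CV
        all_spots = fs.detect_spots(vol, threshold=1.0)
        assert len(all_spots) == 2
        cvs = np.sort(all_spots.table["cv"].to_numpy())
        assert cvs[1] > 2 * cvs[0]  # the spiked object is clearly separable
        filtered = fs.detect_spots(vol, threshold=1.0, cv_max=float(cvs.mean()))
        assert len(filtered) == 1
        assert filtered.table["cv"].iloc[0] == pytest.approx(cvs[0])

    def test_min_size_filter(self):
        vol = np.zeros((10, 20, 20))
        vol[5, 5, 5] = 100.0  # single bright voxel → small object
        vol[4:7, 12:16, 12:16] = 100.0
        both = fs.detect_spots(vol, threshold=1.0, min_size=1)
        assert len(both) == 2
        small, large = np.sort(both.table["volume_vox"].to_numpy())
        assert small < large
        spots = fs.detect_spots(vol, threshold=1.0, min_size=int(small) + 1)
        assert len(spots) == 1
        assert spots.table["volume_vox"].iloc[0] == large

    def test_input_validation(self):
        with pytest.raises(ValueError, match="3D"):
            fs.detect_spots(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="sigma"):
            fs.detect_spots(np.zeros((5, 5, 5)), sigma_low=4.0, sigma_high=2.0)


class TestOverlapClassify:
    def test_identical_sets_fully_overlap(self):
        labels = box_labels((8, 16, 16), [(1, slice(2, 6), slice(2, 8), slice(2, 8))])
        a = spotset_from_labels(labels)
        b = spotset_from_labels(labels.copy())
        res = fs.overlap_classify(a, b)
        assert res.pairs["overlap_fraction"].iloc[0] == pytest.approx(1.0)
        assert res.pairs["double_positive"].iloc[0]

    def test_disjoint_sets_zero_overlap(self):
        a = spotset_from_labels(
            box_labels((8, 16, 16), [(1, slice(2, 5), slice(2, 5), slice(2, 5))])
        )
        b = spotset_from_labels(
            box_labels((8, 16, 16), [(1, slice(2, 5), slice(10, 13), slice(10, 13))])
        )
        res = fs.overlap_classify(a, b)
        assert res.pairs["overlap_fraction"].iloc[0] == 0.0
        assert not res.pairs["double_positive"].iloc[0]

    def test_exactly_forty_percent_is_not_double_positive(self):
        # A = 10 voxels in a row; B covers exactly 4 of them and 6 others
        # → both directional fractions are exactly 0.40
        a_lab = box_labels((4, 4, 12), [(1, slice(1, 2), slice(1, 2), slice(0, 10))])
        b_lab = box_labels((4, 4, 12), [(1, slice(1, 2), slice(2, 3), slice(0, 6))])
        b_lab[1, 1, 6:10] = 1  # 4 shared voxels, |B| = 10
        a = spotset_from_labels(a_lab)
        b = spotset_from_labels(b_lab)
        res = fs.overlap_classify(a, b, threshold=0.40)
        assert res.pairs["overlap_fraction"].iloc[0] == pytest.approx(0.40)
        assert res.pairs["frac_b_in_a"].iloc[0] == pytest.approx(0.40)
        assert not res.pairs["double_positive"].iloc[0]
        # one extra shared voxel pushes it over the strict threshold
        b_lab2 = b_lab.copy()
        b_lab2[1, 1, 5] = 1
        b_lab2[1, 2, 5] = 0
        res2 = fs.overlap_classify(a, spotset_from_labels(b_lab2), threshold=0.40)
        assert res2.pairs["double_positive"].iloc[0]

    def test_shrinking_b_never_increases_overlap(self):
        rng = np.random.default_rng(0)
        shape = (6, 20, 20)
        a = spotset_from_labels(
            box_labels(shape, [(1, slice(1, 5), slice(2, 12), slice(2, 12))])
        )
        b_lab = box_labels(shape, [(1, slice(1, 5), slice(6, 16), slice(6, 16))])
        prev = fs.overlap_classify(a, spotset_from_labels(b_lab)).pairs[
            "overlap_fraction"
        ].iloc[0]
        for _ in range(5):
            vox = np.argwhere(b_lab > 0)
            drop = vox[rng.choice(len(vox), size=len(vox) // 3, replace=False)]
            b_lab[drop[:, 0], drop[:, 1], drop[:, 2]] = 0
            if not (b_lab > 0).any():
                break
            frac = fs.overlap_classify(a, spotset_from_labels(b_lab)).pairs[
                "overlap_fraction"
            ].iloc[0]
            assert frac <= prev + 1e-12
            prev = frac

    def test_relabeling_invariance_of_double_positive_count(self):
        shape = (6, 24, 24)
        a_lab = box_labels(shape, [
            (1, slice(1, 5), slice(2, 8), slice(2, 8)),
            (2, slice(1, 5), slice(12, 18), slice(12, 18)),
        ])
        b_lab = box_labels(shape, [
            (1, slice(1, 5), slice(3, 9), slice(3, 9)),
            (2, slice(1, 5), slice(13, 19), slice(13, 19)),
        ])
        res1 = fs.overlap_classify(spotset_from_labels(a_lab), spotset_from_labels(b_lab))
        # swap the two B labels
        b_sw = np.where(b_lab == 1, 2, np.where(b_lab == 2, 1, 0))
        res2 = fs.overlap_classify(spotset_from_labels(a_lab), spotset_from_labels(b_sw))
        assert res1.n_double_positive == res2.n_double_positive

    def test_grid_mismatch_raises(self):
        a = spotset_from_labels(np.zeros((4, 8, 8), dtype=np.int32))
        b = spotset_from_labels(np.zeros((4, 8, 9), dtype=np.int32))
        with pytest.raises(ValueError, match="grids differ"):
            fs.overlap_classify(a, b)

    def test_intensity_rescaling_does_not_change_overlap(self):
        cfg = fs.ImageSimConfig(
            shape=(16, 48, 48), pairs=[fs.SpotPairSpec(center=(8, 24, 20), overlap=0.5)]
        )
        stack, _ = fs.simulate_image_stack(cfg)
        a1 = fs.detect_spots(stack[0])
        b1 = fs.detect_spots(stack[1])
        a2 = fs.detect_spots(stack[0] * 13.7)
        b2 = fs.detect_spots(stack[1] * 13.7)
        f1 = fs.overlap_classify(a1, b1).pairs["overlap_fraction"]
        f2 = fs.overlap_classify(a2, b2).pairs["overlap_fraction"]
        np.testing.assert_allclose(f1, f2)


class TestContainment:
    def _vesicles(self, shape=(6, 30, 30), n=5):
        boxes = [
            (i + 1, slice(1, 5), slice(1 + 5 * i, 5 + 5 * i), slice(2, 6))
            for i in range(n)
        ]
        return spotset_from_labels(box_labels(shape, boxes))

    def test_all_contain(self):
        ves = self._vesicles()
        cargo_lab = np.zeros((6, 30, 30), dtype=np.int32)
        for i in range(5):
            cargo_lab[2:4, 2 + 5 * i : 4 + 5 * i, 3:5] = i + 1
        assert fs.containment_percent(ves, spotset_from_labels(cargo_lab)) == 100.0

    def test_no_cargo_gives_zero(self):
        ves = self._vesicles()
        empty = spotset_from_labels(np.zeros((6, 30, 30), dtype=np.int32))
        assert fs.containment_percent(ves, empty) == 0.0

    def test_partial_containment_fraction(self):
        ves = self._vesicles(n=10, shape=(6, 55, 55))
        cargo_lab = np.zeros((6, 55, 55), dtype=np.int32)
        for i in range(4):  # cargo inside 4 of 10 vesicles
            cargo_lab[2:4, 2 + 5 * i : 4 + 5 * i, 3:5] = i + 1
        assert fs.containment_percent(ves, spotset_from_labels(cargo_lab)) == pytest.approx(40.0)

    def test_empty_vesicle_set_raises(self):
        empty = spotset_from_labels(np.zeros((4, 8, 8), dtype=np.int32))
        with pytest.raises(ValueError, match="undefined"):
            fs.containment_percent(empty, empty)


class TestLineProfile:
    def test_constant_image_gives_flat_profile(self):
        vol = np.full((10, 20, 20), 42.0)
        prof = fs.line_profile(vol, (5, 5, 2), (5, 5, 18), spacing_um=1.0)
        np.testing.assert_allclose(prof.intensities, 42.0)

    def test_six_micron_segment_at_tenth_micron_spacing(self):
        vol = np.zeros((10, 20, 80))
        prof = fs.line_profile(
            vol, (0.5, 0.5, 0.5), (0.5, 0.5, 6.5), spacing_um=0.1,
            voxel_size_um=(0.2, 0.1, 0.1),
        )
        assert prof.n_samples == 61  # round(6 / 0.1) + 1

    def test_out_of_bounds_raises(self):
        vol = np.zeros((10, 20, 20))
        with pytest.raises(ValueError, match="bounds"):
            fs.line_profile(vol, (5, 5, 5), (5, 5, 50), spacing_um=1.0)

    def test_coincident_peaks_through_colocalized_pair(self):
        cfg = fs.ImageSimConfig(
            shape=(16, 48, 48),
            pairs=[fs.SpotPairSpec(center=(8, 24, 24), overlap=1.0)],
            psf_sigma=1.0,
        )
        stack, _ = fs.simulate_image_stack(cfg)
        prof = fs.line_profile(
            stack, (8 * 0.2, 24 * 0.1, 1.0), (8 * 0.2, 24 * 0.1, 3.8),
            spacing_um=0.1, voxel_size_um=(0.2, 0.1, 0.1),
        )
        peaks = prof.intensities.argmax(axis=1)
        assert abs(int(peaks[0]) - int(peaks[1])) <= 1


class TestSimulatorClosure:
    def test_detection_recovers_count_and_overlap(self):
        targets = [0.0, 0.3, 0.5, 0.8]
        centers = [(12, 20, 20), (12, 20, 64), (12, 70, 20), (12, 70, 64)]
        cfg = fs.ImageSimConfig(
            shape=(24, 96, 96),
            pairs=[fs.SpotPairSpec(center=c, overlap=t)
                   for c, t in zip(centers, targets)],
        )
        stack, truth = fs.simulate_image_stack(cfg)
        spots_a = fs.detect_spots(stack[0])
        spots_b = fs.detect_spots(stack[1])
        assert len(spots_a) == len(targets)
        assert len(spots_b) == len(targets)
        res = fs.overlap_classify(spots_a, spots_b)
        # match detected A spots to ground-truth pairs by position
        truth_a = truth[truth.channel == "A"].reset_index(drop=True)
        for _, spot in spots_a.table.iterrows():
            d = np.linalg.norm(
                truth_a[["z", "y", "x"]].to_numpy()
                - spot[["centroid_z", "centroid_y", "centroid_x"]].to_numpy(),
                axis=1,
            )
            want = truth_a["overlap"].iloc[int(d.argmin())]
            got = res.pairs.loc[
                res.pairs.label_a == spot["label"], "overlap_fraction"
            ].iloc[0]
            assert got == pytest.approx(want, abs=0.05)

    def test_identical_specs_give_full_overlap(self):
        cfg = fs.ImageSimConfig(
            shape=(16, 40, 40),
            spots_a=[fs.SpotSpec(center=(8, 20, 20), radius=4)],
            spots_b=[fs.SpotSpec(center=(8, 20, 20), radius=4)],
        )
        stack, _ = fs.simulate_image_stack(cfg)
        res = fs.overlap_classify(fs.detect_spots(stack[0]), fs.detect_spots(stack[1]))
        assert res.pairs["overlap_fraction"].iloc[0] == pytest.approx(1.0)

    def test_no_spots_noise_only(self):
        cfg = fs.ImageSimConfig(shape=(8, 16, 16), gauss_noise_sd=1.0, seed=3)
        stack, truth = fs.simulate_image_stack(cfg)
        assert truth.empty
        assert stack.shape == (2, 8, 16, 16)

    def test_unreachable_overlap_raises(self):
        with pytest.raises(ValueError, match="unreachable"):
            fs.simulate_image_stack(
                fs.ImageSimConfig(
                    shape=(24, 48, 48),
                    pairs=[fs.SpotPairSpec(center=(12, 24, 24), overlap=1.0,
                                           radius_a=5.0, radius_b=2.0)],
                )
            )

    def test_determinism_with_noise(self):
        cfg = fs.ImageSimConfig(
            shape=(12, 32, 32),
            pairs=[fs.SpotPairSpec(center=(6, 16, 14), overlap=0.5)],
            poisson_noise=True, gauss_noise_sd=2.0, seed=12,
        )
        s1, _ = fs.simulate_image_stack(cfg)
        s2, _ = fs.simulate_image_stack(cfg)
        np.testing.assert_array_equal(s1, s2)

    def test_stack_io_round_trip(self, tmp_path):
        cfg = fs.ImageSimConfig(shape=(8, 24, 24),
                                spots_a=[fs.SpotSpec(center=(4, 12, 12), radius=3)])
        stack, _ = fs.simulate_image_stack(cfg)
        path = tmp_path / "stack.tif"
        fs.write_stack(path, stack, cfg.voxel_size_um)
        back, voxel = fs.read_stack(path)
        np.testing.assert_array_equal(back, stack)
        assert voxel == cfg.voxel_size_um

    def test_brute_force_sphere_overlap_matches_search(self):
        # independent voxel-counting oracle for the distance search
        for target in (0.25, 0.5, 0.75):
            d = fs.distance_for_overlap(4.0, 4.0, target)
            n = 24
            a = fs.sphere_mask((n, n, n), (12, 12, 12 - d / 2), 4.0)
            b = fs.sphere_mask((n, n, n), (12, 12, 12 + d / 2), 4.0)
            assert (a & b).sum() / a.sum() == pytest.approx(target, abs=0.03)
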