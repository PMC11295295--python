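import numpy as np
import pytest

from tractprf import subdivision as sub
from tractprf.io_formats import LabelMap, StreamlineSet, VolumeGrid


def _label_map(ecc, angle):
    n = len(ecc)
    coords = np.column_stack([np.zeros(n), np.arange(n, dtype=float), np.zeros(n)])
    return LabelMap(coordinates=coords, eccentricity_deg=ecc, polar_angle_deg=angle)


class TestLabelSubfields:
    @pytest.mark.parametrize(
        "ecc,angle,expected",
        [
            (2.0, 120.0, "FVF"),   # eccentricity rule dominates the angle
            (4.2, 169.0, "PLVF"),
            (4.2, 45.0, "PUVF"),
            (3.0, 10.0, "FVF"),    # boundary: ecc <= 3 is foveal
            (30.0, 100.0, "PLVF"),
            (5.0, 180.0, "PLVF"),  # hemifield edge closed
        ],
    )
    def test_rule_examples(self, ecc, angle, expected):
        lm = sub.label_subfields(_label_map(np.array([ecc]), np.array([angle])))
        assert lm.subfield_names[lm.subfield_id[0]] == expected

    def test_beyond_thirty_degrees_unlabelled(self):
        lm = sub.label_subfields(_label_map(np.array([31.0]), np.array([45.0])))
        assert lm.subfield_id[0] == -1

    def test_angle_outside_hemifield_rejected(self):
        with pytest.raises(ValueError, match="polar angle"):
            sub.label_subfields(_label_map(np.array([5.0]), np.array([200.0])))


def _assignment_setup():
    """Three labelled locations, one per subfield, well separated."""
    coords = np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
    lm = LabelMap(
        coordinates=coords,
        eccentricity_deg=np.array([1.0, 10.0, 10.0]),
        polar_angle_deg=np.array([45.0, 45.0, 135.0]),
    )
    return sub.label_subfields(lm)


class TestAssignStreamlines:
    def test_exact_termination(self):
        lm = _assignment_setup()
        tract = StreamlineSet(streamlines=[np.array([[0.0, 0, 50], [0.0, 0, 0]])])
        per, unassigned, idx = sub.assign_streamlines(tract, lm)
        assert "FVF" in per and per["FVF"].count == 1
        assert unassigned is None

    def test_beyond_threshold_unassigned(self):
        lm = _assignment_setup()
        tract = StreamlineSet(streamlines=[np.array([[0.0, 0, 50], [0.0, 0, 3.0]])])
        per, unassigned, idx = sub.assign_streamlines(tract, lm, max_dist_mm=2.0)
        assert per == {}
        assert unassigned.count == 1
        assert idx[0] == -1

    def test_toy_anatomy_assignment_matches_design(self, toy_anatomy_clean):
        anat = toy_anatomy_clean
        lm = sub.label_subfields(anat.labels)
        _, unassigned, idx = sub.assign_streamlines(anat.streamlines, lm)
        assert unassigned is None
        names = [lm.subfield_names[i] for i in idx]
        designed = [anat.subfield_names[i] for i in anat.designed_subfield]
        assert names == designed

    def test_matches_all_pairs_oracle(self):
        """Assignment on a random tract equals an exhaustive distance scan."""
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 30, (40, 3))
        lm = sub.label_subfields(
            LabelMap(
                coordinates=coords,
                eccentricity_deg=rng.uniform(0, 28, 40),
                polar_angle_deg=rng.uniform(0, 180, 40),
            )
        )
        tract = StreamlineSet(
            streamlines=[rng.uniform(0, 30, (8, 3)) for _ in range(50)]
        )
        _, _, idx = sub.assign_streamlines(tract, lm, max_dist_mm=2.0)
        for s, got in zip(tract, idx):
            d = np.linalg.norm(coords[None, :, :] - np.stack([s[0], s[-1]])[:, None, :],
                               axis=2)
            end = np.argmin(d.min(axis=1))
            j = np.argmin(d[end])
            expected = lm.subfield_id[j] if d[end, j] < 2.0 else -1
            assert got == expected

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 20, (30, 3))
        lm = sub.label_subfields(
            LabelMap(
                coordinates=coords,
                eccentricity_deg=rng.uniform(0, 28, 30),
                polar_angle_deg=rng.uniform(0, 180, 30),
            )
        )
        tract = StreamlineSet(
            streamlines=[rng.uniform(0, 20, (6, 3)) for _ in range(40)]
        )
        counts = []
        for dist in (1.0, 2.0, 4.0, 8.0):
            _, _, idx = sub.assign_streamlines(tract, lm, max_dist_mm=dist)
            counts.append((idx >= 0).sum())
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_empty_tract_rejected(self):
        with pytest.raises(ValueError):
            sub.assign_streamlines(StreamlineSet(streamlines=[]), _assignment_setup())


class TestTrackWeightMap:
    def _grid(self, n=10):
        return VolumeGrid(data=np.zeros((n, n, n)), affine=np.eye(4))

    def test_straight_streamline_marks_five_voxels(self):
        grid = self._grid()
        s = np.array([[2.0, 5.0, 5.0], [6.0, 5.0, 5.0]])  # along +x through 5 voxels
        tw = sub.track_weight_map(StreamlineSet(streamlines=[s]), grid)
        assert tw.data.sum() == 5
        assert np.all(tw.data[2:7, 5, 5] == 1)

    def test_duplicate_streamlines_count_twice(self):
        grid = self._grid()
        s = np.array([[2.0, 5.0, 5.0], [6.0, 5.0, 5.0]])
        tw = sub.track_weight_map(StreamlineSet(streamlines=[s, s.copy()]), grid)
        assert np.all(tw.data[2:7, 5, 5] == 2)

    def test_matches_dense_resampling_oracle(self):
        """Counts on a random bundle equal a brute-force point-in-voxel count
        after independent 0.1 mm resampling."""
        rng = np.random.default_rng(21)
        grid = VolumeGrid(data=np.zeros((15, 15, 15)), affine=np.eye(4))
        streamlines = [
            np.cumsum(rng.uniform(-1.5, 2.0, (12, 3)), axis=0) + [3.0, 7.0, 7.0]
            for _ in range(8)
        ]
        tw = sub.track_weight_map(
            StreamlineSet(streamlines=streamlines), grid, step_mm=0.1
        )
        oracle = np.zeros((15, 15, 15), dtype=int)
        for s in streamlines:
            visited = set()
            for p0, p1 in zip(s[:-1], s[1:]):
                n = int(np.ceil(np.linalg.norm(p1 - p0) / 0.1)) + 1
                for t in np.linspace(0.0, 1.0, n):
                    p = (1 - t) * p0 + t * p1
                    ijk = tuple(int(round(v)) for v in p)
                    if all(0 <= v < 15 for v in ijk):
                        visited.add(ijk)
            for ijk in visited:
                oracle[ijk] += 1
        np.testing.assert_array_equal(tw.data, oracle)


class TestReallocateOverlaps:
    def _bundle(self, name, weights):
        grid = VolumeGrid(data=np.asarray(weights), affine=np.eye(4))
        return sub.SubBundle(subfield=name, streamlines=None, track_weight=grid)

    def test_argmax_wins(self):
        w = np.zeros((3, 3, 3), dtype=int)
        w_f, w_p = w.copy(), w.copy()
        w_f[1, 1, 1] = 5
        w_p[1, 1, 1] = 2
        out = sub.reallocate_overlaps(
            [self._bundle("FVF", w_f), self._bundle("PUVF", w_p)]
        )
        assert out[0].mask_standard.data[1, 1, 1] == 1
        assert out[1].mask_standard.data[1, 1, 1] == 0

    def test_tie_goes_to_lexicographically_smallest(self):
        w = np.zeros((3, 3, 3), dtype=int)
        w_a, w_b = w.copy(), w.copy()
        w_a[0, 0, 0] = 3
        w_b[0, 0, 0] = 3
        out = sub.reallocate_overlaps(
            [self._bundle("PUVF", w_a), self._bundle("FVF", w_b)]
        )
        by_name = {b.subfield: b for b in out}
        assert by_name["FVF"].mask_standard.data[0, 0, 0] == 1
        assert by_name["PUVF"].mask_standard.data[0, 0, 0] == 0

    def test_disjoint_inputs_unchanged(self):
        w_a = np.zeros((3, 3, 3), dtype=int)
        w_b = np.zeros((3, 3, 3), dtype=int)
        w_a[0, 0, 0] = 2
        w_b[2, 2, 2] = 4
        out = sub.reallocate_overlaps(
            [self._bundle("FVF", w_a), self._bundle("PLVF", w_b)]
        )
        np.testing.assert_array_equal(out[0].mask_standard.data, w_a > 0)
        np.testing.assert_array_equal(out[1].mask_standard.data, w_b > 0)

    def test_masks_disjoint_after_reallocation(self):
        rng = np.random.default_rng(2)
        bundles = [
            self._bundle(name, rng.integers(0, 4, (6, 6, 6)))
            for name in ("FVF", "PLVF", "PUVF")
        ]
        out = sub.reallocate_overlaps(bundles)
        total = sum(b.mask_standard.data.astype(int) for b in out)
        assert total.max() <= 1


class TestWMMasks:
    def _vol(self, data):
        return VolumeGrid(data=np.asarray(data, dtype=np.uint8), affine=np.eye(4))

    def test_empty_gm_leaves_wm(self):
        wm = np.ones((5, 5, 5), dtype=np.uint8)
        std, strict = sub.make_wm_masks(self._vol(np.zeros((5, 5, 5))), self._vol(wm))
        np.testing.assert_array_equal(std.data, wm)
        np.testing.assert_array_equal(strict.data, wm)

    def test_single_voxel_matches_brute_force_cross(self):
        """One GM voxel on a 9^3 WM-filled grid: 6-connected dilation removes
        the 7-voxel cross (standard) and the 25-voxel radius-2 cross (strict)."""
        gm = np.zeros((9, 9, 9), dtype=np.uint8)
        gm[4, 4, 4] = 1
        wm = np.ones((9, 9, 9), dtype=np.uint8)
        std, strict = sub.make_wm_masks(self._vol(gm), self._vol(wm))
        assert (wm.sum() - std.data.sum()) == 7
        assert (wm.sum() - strict.data.sum()) == 25
        # brute force: Manhattan balls of radius 1 and 2
        ii, jj, kk = np.meshgrid(*[np.arange(9)] * 3, indexing="ij")
        manhattan = np.abs(ii - 4) + np.abs(jj - 4) + np.abs(kk - 4)
        np.testing.assert_array_equal(std.data, (manhattan > 1).astype(np.uint8))
        np.testing.assert_array_equal(strict.data, (manhattan > 2).astype(np.uint8))

    def test_distant_wm_untouched_and_strict_subset(self):
        gm = np.zeros((9, 9, 9), dtype=np.uint8)
        gm[0, 0, 0] = 1
        wm = np.zeros((9, 9, 9), dtype=np.uint8)
        wm[6:, 6:, 6:] = 1
        std, strict = sub.make_wm_masks(self._vol(gm), self._vol(wm))
        np.testing.assert_array_equal(std.data, wm)
        np.testing.assert_array_equal(strict.data, wm)
        assert np.all(strict.data <= std.data)

    def test_non_binary_rejected(self):
        bad = np.full((3, 3, 3), 2, dtype=np.uint8)
        with pytest.raises(ValueError, match="binary"):
            sub.make_wm_masks(self._vol(bad), self._vol(np.ones((3, 3, 3))))


class TestFinalizeSubject:
    def _bundle_with_voxels(self, name, n_std, n_strict):
        std = np.zeros((5, 5, 5), dtype=np.uint8)
        std.flat[:n_std] = 1
        strict = np.zeros((5, 5, 5), dtype=np.uint8)
        strict.flat[:n_strict] = 1
        return sub.SubBundle(
            subfield=name, streamlines=None,
            mask_standard=VolumeGrid(data=std, affine=np.eye(4)),
            mask_strict=VolumeGrid(data=strict, affine=np.eye(4)),
        )

    def test_all_above_threshold_included(self):
        bundles = [self._bundle_with_voxels(n, 11, 11) for n in ("FVF", "PLVF")]
        included, report = sub.finalize_subject(bundles)
        assert included
        assert report["FVF"]["standard_voxels"] == 11

    def test_exactly_ten_voxels_excluded(self):
        bundles = [
            self._bundle_with_voxels("FVF", 11, 11),
            self._bundle_with_voxels("PLVF", 10, 11),
        ]
        included, _ = sub.finalize_subject(bundles)
        assert not included

    def test_empty_bundle_excluded(self):
        included, _ = sub.finalize_subject([self._bundle_with_voxels("FVF", 0, 0)])
        assert not included


class TestEndToEndSubdivision:
    def test_toy_anatomy_full_pipeline(self, toy_anatomy_clean):
        """Assignment -> track weights -> reallocation -> WM constraint ->
        inclusion, on the zero-jitter toy anatomy."""
        anat = toy_anatomy_clean
        lm = sub.label_subfields(anat.labels)
        per_subfield, unassigned, _ = sub.assign_streamlines(anat.streamlines, lm)
        assert unassigned is None
        bundles = [
            sub.SubBundle(
                subfield=name, streamlines=sls,
                track_weight=sub.track_weight_map(sls, anat.wm_mask, step_mm=0.25),
            )
            for name, sls in per_subfield.items()
        ]
        bundles = sub.reallocate_overlaps(bundles)
        total = sum(b.mask_standard.data.astype(int) for b in bundles)
        assert total.max() <= 1  # disjoint after reallocation
        std, strict = sub.make_wm_masks(anat.gm_mask, anat.wm_mask)
        bundles = [sub.apply_wm_constraint(b, std, strict) for b in bundles]
        for b in bundles:
            assert np.all(b.mask_strict.data <= b.mask_standard.data)
        included, report = sub.finalize_subject(bundles, min_voxels=10)
        assert set(report) == {"FVF", "PLVF", "PUVF"}
        for entry in report.values():
            assert entry["standard_voxels"] >= entry["strict_voxels"]
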