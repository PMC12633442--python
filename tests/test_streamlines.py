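"""Streamline geometry, TCK/NIfTI round trips, voxelization, and bundle cleaning."""
import numpy as np
import pytest

from safconn.streamlines import (
    Bundle,
    GridBoundsError,
    GridSpec,
    StreamlineError,
    TckFormatError,
    TractSpec,
    as_streamline,
    compute_density_map,
    filter_by_length,
    read_density_nifti,
    read_tck,
    reject_outliers,
    streamline_length,
    streamline_voxels,
    write_density_nifti,
    write_tck,
)


def line(*points):
    return np.asarray(points, dtype=np.float64)


class TestStreamlineGeometry:
    @pytest.mark.parametrize(
        "points,expected",
        [
            (line((0, 0, 0), (10, 0, 0)), 10.0),
            (line((0, 0, 0), (4, 0, 0), (10, 0, 0)), 10.0),  # collinear additivity
            (line((0, 0, 0), (3, 0, 0), (3, 4, 0)), 7.0),  # right angle 3 + 4
        ],
    )
    def test_length(self, points, expected):
        assert streamline_length(points) == pytest.approx(expected)

    def test_invalid_streamlines_rejected(self):
        with pytest.raises(StreamlineError):
            as_streamline([[0, 0, 0]])
        with pytest.raises(StreamlineError):
            as_streamline([[0, 0, 0], [np.nan, 0, 0]])
        with pytest.raises(StreamlineError):
            as_streamline([[1, 1, 1], [1, 1, 1]])

    def test_filter_by_length_keeps_short_streamlines_in_order(self):
        bundle = Bundle(
            streamlines=[
                line((0, 0, 0), (30, 0, 0)),
                line((0, 0, 0), (50, 0, 0)),
                line((0, 0, 0), (130, 0, 0)),
            ]
        )
        out = filter_by_length(bundle, TractSpec(max_length_mm=125.0))
        assert [streamline_length(s) for s in out.streamlines] == [30.0, 50.0]

    def test_filter_by_length_is_idempotent(self):
        bundle = Bundle(
            streamlines=[line((0, 0, 0), (l, 0, 0)) for l in (10, 60, 90, 124, 126)]
        )
        spec = TractSpec(max_length_mm=125.0)
        once = filter_by_length(bundle, spec)
        twice = filter_by_length(once, spec)
        assert len(once) == 4
        assert [id(s) for s in once.streamlines] == [id(s) for s in twice.streamlines]

    def test_tract_spec_bounds(self):
        with pytest.raises(ValueError):
            TractSpec(max_length_mm=30.0)
        assert TractSpec().max_total_streamlines == 2000


class TestTckIO:
    def test_round_trip_preserves_counts_and_coordinates(self, tmp_path):
        bundle = Bundle(
            streamlines=[
                line((0, 0, 0), (1, 2, 3)),
                line((5, 5, 5), (6, 5, 5), (7, 8, 9)),
                line((0, 0, 1), (0, 0, 2), (0, 1, 3), (2, 2, 2)),
            ]
        )
        path = write_tck(bundle, tmp_path / "b.tck")
        back = read_tck(path)
        assert len(back) == 3
        assert [len(s) for s in back.streamlines] == [2, 3, 4]
        for a, b in zip(bundle.streamlines, back.streamlines):
            np.testing.assert_allclose(a, b, atol=1e-5)

    def test_empty_bundle_round_trip(self, tmp_path):
        path = write_tck(Bundle(streamlines=[]), tmp_path / "empty.tck")
        assert len(read_tck(path)) == 0

    def test_missing_magic_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.tck"
        bad.write_bytes(b"definitely not a tractogram\n")
        with pytest.raises(TckFormatError):
            read_tck(bad)


class TestVoxelization:
    def test_straight_line_traverses_five_voxels(self, small_grid):
        bundle = Bundle(streamlines=[line((0.5, 0.5, 0.5), (4.5, 0.5, 0.5))])
        dmap = compute_density_map(bundle, small_grid)
        assert dmap.n_support == 5
        assert np.all(dmap.counts[:5, 0, 0] == 1)

    def test_two_identical_streamlines_double_counts(self, small_grid):
        s = line((0.5, 0.5, 0.5), (4.5, 0.5, 0.5))
        one = compute_density_map(Bundle(streamlines=[s]), small_grid)
        two = compute_density_map(Bundle(streamlines=[s, s.copy()]), small_grid)
        assert np.array_equal(two.counts, 2 * one.counts)

    def test_empty_bundle_gives_zero_map(self, small_grid):
        dmap = compute_density_map(Bundle(streamlines=[]), small_grid)
        assert dmap.counts.sum() == 0

    def test_out_of_bounds_point_reports_streamline(self, small_grid):
        bundle = Bundle(
            streamlines=[
                line((1, 1, 1), (2, 2, 2)),
                line((1, 1, 1), (9.5, 1, 1)),
            ]
        )
        with pytest.raises(GridBoundsError, match="streamline 1"):
            compute_density_map(bundle, small_grid)

    def test_diagonal_segment_counts_every_traversed_voxel(self, small_grid):
        # a diagonal in the xy-plane crossing voxel boundaries between corners
        s = line((0.25, 0.75, 0.5), (3.75, 3.25, 0.5))
        vox = streamline_voxels(s, small_grid)
        assert len(vox) >= 4  # strictly more than the endpoints' voxels
        assert {tuple(v) for v in vox} >= {(0, 0, 0), (3, 3, 0)}

    def test_supersampling_oracle(self, small_grid):
        """Exact segment traversal matches brute-force dense supersampling.

        A coarse sampling can only miss voxels the segment barely clips, never
        find extra ones; at a sufficiently fine step the two sets coincide.
        """
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_pts = rng.integers(2, 6)
            s = rng.uniform(0.3, 7.7, size=(n_pts, 3))
            got = {tuple(v) for v in streamline_voxels(s, small_grid)}
            for divisor, exact in ((20, False), (400, True)):
                expected = set()
                step = small_grid.voxel_size / divisor
                for a, b in zip(s[:-1], s[1:]):
                    seg_len = np.linalg.norm(b - a)
                    n = max(2, int(np.ceil(seg_len / step)) + 1)
                    for t in np.linspace(0.0, 1.0, n):
                        p = a + t * (b - a)
                        expected.add(tuple(small_grid.world_to_voxel(p)))
                assert got >= expected
                if exact:
                    assert got == expected


class TestOutlierRejection:
    def test_displaced_arc_removed(self, u_arc_bundle):
        bundle = u_arc_bundle(n_streamlines=20)
        outlier = bundle.streamlines[0] + np.array([0.0, 30.0, 0.0])
        bundle.streamlines.append(outlier)
        cleaned = reject_outliers(bundle, threshold_factor=3.0)
        assert len(cleaned) == 20
        assert not any(np.allclose(s, outlier) for s in cleaned.streamlines)

    def test_identical_bundle_unchanged(self, u_arc_bundle):
        bundle = u_arc_bundle(n_streamlines=10)
        assert len(reject_outliers(bundle, 3.0)) == 10

    def test_small_bundles_returned_unchanged(self, u_arc_bundle):
        empty = Bundle(streamlines=[])
        assert len(reject_outliers(empty, 3.0)) == 0
        single = Bundle(streamlines=[u_arc_bundle(1).streamlines[0]])
        assert len(reject_outliers(single, 3.0)) == 1

    def test_output_is_subset_and_stable_under_reapplication(self, u_arc_bundle):
        bundle = u_arc_bundle(n_streamlines=15, jitter=0.8)
        bundle.streamlines.append(bundle.streamlines[0] + np.array([0.0, 25.0, 0.0]))
        once = reject_outliers(bundle, 3.0)
        ids = {id(s) for s in bundle.streamlines}
        assert all(id(s) in ids for s in once.streamlines)
        twice = reject_outliers(once, 3.0)
        assert len(twice) == len(once)


class TestDensityNifti:
    def test_round_trip_preserves_counts_and_grid(self, tmp_path, map_builder):
        dmap = map_builder({(1, 2, 3): 4, (5, 5, 5): 1})
        path = write_density_nifti(dmap, tmp_path / "d.nii.gz")
        back = read_density_nifti(path)
        assert back.grid == dmap.grid
        assert np.array_equal(back.counts, dmap.counts)

    def test_one_mm_grid_has_unit_affine_diagonal(self, tmp_path, map_builder):
        import nibabel as nib

        path = write_density_nifti(map_builder({(0, 0, 0): 1}), tmp_path / "d.nii.gz")
        img = nib.load(str(path))
        np.testing.assert_allclose(np.diag(img.affine)[:3], [1.0, 1.0, 1.0])

    def test_anisotropic_volume_rejected(self, tmp_path):
        import nibabel as nib

        affine = np.diag([1.0, 2.0, 1.0, 1.0])
        img = nib.Nifti1Image(np.zeros((4, 4, 4), dtype=np.int32), affine)
        nib.save(img, str(tmp_path / "aniso.nii.gz"))
        with pytest.raises(ValueError, match="isotropic"):
            read_density_nifti(tmp_path / "aniso.nii.gz")

    def test_grid_spec_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            GridSpec(voxel_size=0.0)
        with pytest.raises(ValueError):
            GridSpec(shape=(0, 4, 4))
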