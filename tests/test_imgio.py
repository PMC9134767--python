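import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

from chromasym.errors import ContractError, EmptyRegionError, FormatError
from chromasym.imgio import (
    CellAnnotation,
    ImageStack,
    MeasurementTable,
    RegionOfInterest,
    largest_inscribed_square,
    max_projection,
    rasterize_roi,
    read_rois_csv,
    read_rois_json,
    read_stack,
    validate_pairing,
    write_mask,
    write_rois_csv,
    write_rois_json,
    write_stack,
)
from conftest import exhaustive_largest_square, loop_raw_sum, point_in_polygon


class TestImageStack:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError, match="shape"):
            ImageStack({
                "a": np.zeros((2, 4, 4), dtype=np.uint16),
                "b": np.zeros((2, 4, 5), dtype=np.uint16),
            })

    def test_range_enforced(self):
        with pytest.raises(ContractError, match="intensities"):
            ImageStack({"a": np.full((1, 2, 2), 300, dtype=np.int32)}, bit_depth=8)

    def test_voxel_size_positive(self):
        with pytest.raises(ContractError, match="voxel_size"):
            ImageStack({"a": np.zeros((1, 2, 2), dtype=np.uint8)}, bit_depth=8,
                       voxel_size=(0, 1, 1))

    def test_missing_channel(self, small_stack):
        from chromasym.errors import MissingChannelError

        with pytest.raises(MissingChannelError):
            small_stack.channel("nope")


class TestTiffRoundTrip:
    def test_single_channel(self, tmp_path, rng):
        data = rng.integers(0, 65535, size=(4, 8, 10)).astype(np.uint16)
        tifffile.imwrite(tmp_path / "s.tif", data, photometric="minisblack")
        stack = read_stack(tmp_path / "s.tif", channel_names=["H3"])
        assert stack.channel_names == ["H3"]
        assert stack.shape == (4, 8, 10)
        np.testing.assert_array_equal(stack.channel("H3"), data)

    def test_interleaved_two_channels(self, tmp_path, rng):
        planes = rng.integers(0, 65535, size=(8, 6, 6)).astype(np.uint16)
        tifffile.imwrite(tmp_path / "s.tif", planes)
        stack = read_stack(tmp_path / "s.tif", channel_names=["old", "new"])
        assert stack.shape == (4, 6, 6)
        np.testing.assert_array_equal(stack.channel("old"), planes[0::2])
        np.testing.assert_array_equal(stack.channel("new"), planes[1::2])

    def test_write_read_identity(self, tmp_path, small_stack):
        write_stack(small_stack, tmp_path / "s.tif")
        back = read_stack(tmp_path / "s.tif")
        assert back.channel_names == small_stack.channel_names
        assert back.voxel_size == small_stack.voxel_size
        for name in small_stack.channel_names:
            np.testing.assert_array_equal(back.channel(name), small_stack.channel(name))

    def test_plane_count_mismatch(self, tmp_path, rng):
        tifffile.imwrite(tmp_path / "s.tif",
                         rng.integers(0, 100, size=(5, 4, 4)).astype(np.uint16))
        with pytest.raises(FormatError, match="divisible"):
            read_stack(tmp_path / "s.tif", channel_names=["a", "b"])

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            read_stack(tmp_path / "absent.tif")

    def test_ome_tiff(self, tmp_path, rng):
        data = rng.integers(0, 65535, size=(2, 3, 8, 8)).astype(np.uint16)
        tifffile.imwrite(tmp_path / "s.ome.tif", data, ome=True,
                         metadata={"axes": "CZYX"})
        stack = read_stack(tmp_path / "s.ome.tif", channel_names=["old", "new"])
        assert stack.shape == (3, 8, 8)
        np.testing.assert_array_equal(stack.channel("new"), data[1])

    def test_mask_roundtrip(self, tmp_path, rng):
        mask = rng.random((9, 9)) > 0.5
        write_mask(mask, tmp_path / "m.tif")
        np.testing.assert_array_equal(tifffile.imread(tmp_path / "m.tif") > 0, mask)


class TestRasterize:
    def test_tiny_circle_single_pixel(self):
        roi = RegionOfInterest("r", "circle", center=(1.5, 1.5), radius=0.6)
        mask = rasterize_roi(roi, (3, 3))
        assert mask.sum() == 1 and mask[1, 1]

    def test_square_polygon_2x2(self):
        roi = RegionOfInterest(
            "r", "polygon", vertices=[(0, 0), (0, 2), (2, 2), (2, 0)]
        )
        mask = rasterize_roi(roi, (4, 4))
        assert mask.sum() == 4
        assert mask[:2, :2].all()

    def test_polygon_boundary_center_counts_inside(self):
        # pixel (0, 0) center (0.5, 0.5) lies exactly on the left edge
        roi = RegionOfInterest(
            "r", "polygon", vertices=[(0.0, 0.5), (0.0, 3.0), (3.0, 3.0), (3.0, 0.5)]
        )
        mask = rasterize_roi(roi, (3, 3))
        assert mask[0, 0]

    def test_outside_image_raises(self):
        roi = RegionOfInterest("r", "circle", center=(100.0, 100.0), radius=2.0)
        with pytest.raises(EmptyRegionError):
            rasterize_roi(roi, (10, 10))

    def test_polygon_area_vs_monte_carlo(self, rng):
        # irregular star-convex polygon; MC oracle with 1e5 points
        angles = np.sort(rng.uniform(0, 2 * np.pi, 9))
        radii = rng.uniform(5, 14, 9)
        verts = [(20 + r * np.sin(a), 20 + r * np.cos(a)) for a, r in zip(angles, radii)]
        roi = RegionOfInterest("r", "polygon", vertices=verts)
        mask = rasterize_roi(roi, (40, 40))
        pts = rng.uniform(0, 40, size=(100_000, 2))
        inside = sum(point_in_polygon(y, x, verts) for y, x in pts)
        mc_area = inside / len(pts) * 1600
        assert mask.sum() == pytest.approx(mc_area, rel=0.02)


class TestMaxProjection:
    def test_single_slice_identity(self):
        arr = np.arange(6, dtype=np.uint16).reshape(1, 2, 3)
        stack = ImageStack({"c": arr})
        np.testing.assert_array_equal(max_projection(stack, "c"), arr[0])

    def test_two_slice_example(self):
        arr = np.array([[[0, 5]], [[3, 2]]], dtype=np.uint16)
        stack = ImageStack({"c": arr})
        np.testing.assert_array_equal(max_projection(stack, "c"), [[3, 5]])

    def test_matches_pixel_loop(self, small_stack):
        proj = max_projection(small_stack, "old")
        arr = small_stack.channel("old")
        for y in range(arr.shape[1]):
            for x in range(arr.shape[2]):
                assert proj[y, x] == max(arr[z, y, x] for z in range(arr.shape[0]))

    def test_idempotent_and_commutes_with_crop(self, small_stack):
        proj = max_projection(small_stack, "new")
        np.testing.assert_array_equal(proj[2:10, 3:12],
                                      small_stack.channel("new")[:, 2:10, 3:12].max(axis=0))


class TestLargestSquare:
    def test_full_mask(self):
        assert largest_inscribed_square(np.ones((5, 5), dtype=bool)) == (0, 0, 5)

    def test_single_pixel(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 1] = True
        assert largest_inscribed_square(mask) == (2, 1, 1)

    def test_l_shape(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[0:2, 0:4] = True  # horizontal arm
        mask[0:4, 0:2] = True  # vertical arm
        top, left, side = largest_inscribed_square(mask)
        assert side == 2
        assert (top, left) == (0, 0)

    def test_empty_raises(self):
        with pytest.raises(EmptyRegionError):
            largest_inscribed_square(np.zeros((3, 3), dtype=bool))

    def test_against_exhaustive(self, rng):
        for _ in range(30):
            mask = rng.random((rng.integers(3, 12), rng.integers(3, 12))) > 0.35
            if not mask.any():
                continue
            assert largest_inscribed_square(mask) == exhaustive_largest_square(mask)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_result_always_inside(self, seed):
        local = np.random.default_rng(seed)
        mask = local.random((10, 10)) > 0.4
        if not mask.any():
            return
        top, left, side = largest_inscribed_square(mask)
        assert mask[top : top + side, left : left + side].all()


class TestRoiIO:
    def _rois(self):
        return [
            RegionOfInterest("GSC", "circle", center=(10.0, 12.5), radius=4.0,
                             slices=[0, 1, 2], pair_id="p1"),
            RegionOfInterest("outline", "polygon",
                             vertices=[(1, 1), (1, 8), (8, 8)], slices="all"),
        ]

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_roundtrip(self, tmp_path, fmt):
        path = tmp_path / f"rois.{fmt}"
        writer = write_rois_csv if fmt == "csv" else write_rois_json
        reader = read_rois_csv if fmt == "csv" else read_rois_json
        writer(self._rois(), path)
        back = reader(path)
        assert [r.label for r in back] == ["GSC", "outline"]
        assert back[0].center == (10.0, 12.5) and back[0].radius == 4.0
        assert back[0].slices == [0, 1, 2] and back[0].pair_id == "p1"
        assert back[1].slices == "all" and back[1].pair_id is None
        np.testing.assert_allclose(back[1].vertices, [(1, 1), (1, 8), (8, 8)])

    def test_invalid_roi_rejected(self):
        with pytest.raises(ContractError):
            RegionOfInterest("r", "circle", center=(1, 1), radius=0)
        with pytest.raises(ContractError):
            RegionOfInterest("r", "polygon", vertices=[(0, 0), (1, 1)])


class TestAnnotationsAndTables:
    def test_pairing_validation(self):
        good = [
            CellAnnotation("GSC", "telophase", "p1", "stem"),
            CellAnnotation("GB", "telophase", "p1", "diff"),
        ]
        validate_pairing(good)
        bad = good + [CellAnnotation("SG", "telophase", "p1", "SG1")]
        with pytest.raises(ContractError, match="members"):
            validate_pairing(bad)

    def test_measurement_table_duplicate_rejected(self):
        row = dict(pair_id="p", cell_type="GSC", stage="t", measure="ratio",
                   channel="H3", value=1.5, units="")
        with pytest.raises(ContractError, match="duplicate"):
            MeasurementTable([row, row])

    def test_measurement_table_csv_roundtrip(self, tmp_path):
        table = MeasurementTable([
            dict(pair_id="p", cell_type="GSC", stage="t", measure="ratio",
                 channel="H3", value=1.5, units=""),
        ])
        table.to_csv(tmp_path / "t.csv")
        back = MeasurementTable.from_csv(tmp_path / "t.csv")
        assert back.df["value"].iloc[0] == 1.5


def test_loop_raw_sum_oracle_matches_numpy(rng):
    # sanity of the oracle itself on a trivial case
    img = np.arange(12).reshape(3, 4)
    mask = np.ones((3, 4), dtype=bool)
    assert loop_raw_sum(img, mask) == 66
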