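import numpy as np
import pytest

from flydyad import VoxelStack, mirror_average, read_nrrd, threshold_volume, write_nrrd
from flydyad.nrrd_io import NrrdError
from flydyad import nrrd_io
from flydyad.synthetic_data import simulate_voxel_stack
from flydyad.volume_quant import volume_report


def random_stack(rng, shape=(8, 6, 4), scale=1000.0):
    return VoxelStack(intensities=rng.uniform(0, scale, size=shape))


class TestMirrorAverage:
    def test_single_voxel_splits_across_the_midline(self):
        grid = np.zeros((4, 1, 1))
        grid[0, 0, 0] = 10.0
        out = mirror_average(VoxelStack(grid))
        assert out.intensities[0, 0, 0] == 5.0
        assert out.intensities[3, 0, 0] == 5.0
        assert out.intensities[1:3].sum() == 0.0

    def test_symmetric_input_is_a_fixed_point(self, rng):
        half = rng.uniform(0, 100, size=(3, 5, 4))
        sym = np.concatenate([half, half[::-1]], axis=0)
        out = mirror_average(VoxelStack(sym))
        np.testing.assert_array_equal(out.intensities, sym)

    def test_output_exactly_flip_symmetric(self, rng):
        for _ in range(10):
            stacks = [random_stack(rng) for _ in range(3)]
            out = mirror_average(stacks).intensities
            np.testing.assert_array_equal(out, out[::-1, :, :])

    def test_idempotent(self, rng):
        out1 = mirror_average(random_stack(rng))
        out2 = mirror_average(out1)
        np.testing.assert_array_equal(out1.intensities, out2.intensities)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            mirror_average([random_stack(rng, (4, 4, 4)), random_stack(rng, (5, 4, 4))])


class TestThresholdVolume:
    def test_counts_times_voxel_volume(self):
        grid = np.zeros((10, 10, 10))
        grid.flat[:100] = 1000.0
        vol, n = threshold_volume(VoxelStack(grid), threshold=800)
        assert (vol, n) == (100.0, 100)

    def test_all_zero_stack(self):
        vol, n = threshold_volume(VoxelStack(np.zeros((5, 5, 5))), threshold=800)
        assert (vol, n) == (0.0, 0)

    def test_threshold_comparison_is_inclusive(self):
        grid = np.full((2, 2, 2), 800.0)
        _, n = threshold_volume(VoxelStack(grid), threshold=800)
        assert n == 8

    def test_anisotropic_voxel_volume(self):
        grid = np.full((2, 2, 2), 900.0)
        vol, n = threshold_volume(VoxelStack(grid, voxel_size=(0.5, 0.5, 1.0)))
        assert vol == pytest.approx(8 * 0.25)

    def test_monotone_under_threshold_sweep(self, rng):
        stack = random_stack(rng, (12, 12, 8))
        vols = [threshold_volume(stack, th)[1] for th in np.linspace(0, 1100, 20)]
        assert vols == sorted(vols, reverse=True)
        assert vols[0] == stack.intensities.size  # threshold 0 counts everything
        assert vols[-1] == 0  # above the max intensity

    def test_additive_over_disjoint_masks(self, rng):
        stack = random_stack(rng, (10, 10, 4))
        m1 = np.zeros(stack.shape, dtype=bool)
        m2 = np.zeros(stack.shape, dtype=bool)
        m1[:5] = True
        m2[5:] = True
        v1, _ = threshold_volume(stack, 500, mask=m1)
        v2, _ = threshold_volume(stack, 500, mask=m2)
        v, _ = threshold_volume(stack, 500)
        assert v1 + v2 == pytest.approx(v)

    def test_empty_mask_zero_volume(self, rng):
        stack = random_stack(rng)
        vol, n = threshold_volume(stack, 0, mask=np.zeros(stack.shape, dtype=bool))
        assert (vol, n) == (0.0, 0)

    def test_threshold_beyond_bit_depth_rejected(self):
        stack = VoxelStack(np.zeros((2, 2, 2)), bit_depth=8)
        with pytest.raises(ValueError, match="bit"):
            threshold_volume(stack, threshold=800)

    def test_sphere_volume_recovered_exactly_without_noise(self):
        stack, truth = simulate_voxel_stack(
            [((16, 16, 8), 5.0, 1000.0)], shape=(32, 32, 16), noise_sd=0.0
        )
        vol, n = threshold_volume(stack, threshold=800)
        assert n == truth["union_voxels"]

    def test_volume_report_columns(self, rng):
        stack = random_stack(rng)
        rep = volume_report([("s1", "structA", stack, None)], threshold=500)
        assert list(rep.columns) == ["sample", "structure", "threshold", "voxels", "volume_um3"]


class TestNrrdIO:
    def test_round_trip_random_stack(self, tmp_path, rng):
        stack = VoxelStack(
            rng.uniform(0, 4000, size=(7, 5, 3)).astype(np.float32),
            voxel_size=(0.46, 0.46, 1.0),
        )
        p = tmp_path / "s.nrrd"
        write_nrrd(stack, p)
        back = read_nrrd(p)
        np.testing.assert_array_equal(back.intensities, stack.intensities)
        assert back.voxel_size == pytest.approx(stack.voxel_size)

    def test_gzip_encoding_round_trip(self, tmp_path, rng):
        stack = VoxelStack((rng.uniform(0, 4000, size=(6, 6, 6))).astype(np.uint16))
        p = tmp_path / "s.nrrd"
        write_nrrd(stack, p, encoding="gzip")
        back = read_nrrd(p)
        np.testing.assert_array_equal(back.intensities, stack.intensities)
        assert back.bit_depth == 16

    def test_integer_dtype_preserved(self, tmp_path):
        stack = VoxelStack(np.arange(24, dtype=np.uint16).reshape(2, 3, 4))
        p = tmp_path / "s.nrrd"
        write_nrrd(stack, p)
        assert read_nrrd(p).intensities.dtype == np.uint16

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.nrrd"
        p.write_bytes(b"NOTNRRD\n\n")
        with pytest.raises(NrrdError, match="magic"):
            read_nrrd(p)

    def test_non_3d_file_rejected_no_silent_reshape(self, tmp_path):
        p = tmp_path / "2d.nrrd"
        nrrd_io.write(p, np.zeros((4, 4), dtype=np.float32))
        with pytest.raises(NrrdError, match="3-D"):
            read_nrrd(p)

    def test_diagonal_space_directions_parsed(self, tmp_path):
        arr = np.arange(8, dtype=np.uint8).reshape(2, 2, 2)
        header = (
            "NRRD0004\ntype: uint8\ndimension: 3\nsizes: 2 2 2\nencoding: raw\n"
            "space directions: (0.5,0,0) (0,0.5,0) (0,0,2.0)\n\n"
        )
        p = tmp_path / "sd.nrrd"
        p.write_bytes(header.encode() + arr.tobytes(order="F"))
        stack = read_nrrd(p)
        assert stack.voxel_size == pytest.approx((0.5, 0.5, 2.0))

    def test_non_diagonal_space_directions_rejected(self, tmp_path):
        arr = np.zeros((2, 2, 2), dtype=np.uint8)
        header = (
            "NRRD0004\ntype: uint8\ndimension: 3\nsizes: 2 2 2\nencoding: raw\n"
            "space directions: (0.5,0.1,0) (0,0.5,0) (0,0,2.0)\n\n"
        )
        p = tmp_path / "sd.nrrd"
        p.write_bytes(header.encode() + arr.tobytes(order="F"))
        with pytest.raises(NrrdError, match="non-axis-aligned"):
            read_nrrd(p)

    def test_fortran_index_order_matches_convention(self, tmp_path):
        # first listed axis varies fastest in the data block
        arr = np.array([[[1, 2], [3, 4]], [[5, 6], [7, 8]]], dtype=np.uint8)
        p = tmp_path / "o.nrrd"
        nrrd_io.write(p, arr)
        payload = p.read_bytes().split(b"\n\n", 1)[1]
        assert payload[0] == 1 and payload[1] == 5  # x axis fastest
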