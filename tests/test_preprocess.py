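import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from advseg.preprocess import (
    ALL_AUGMENTS,
    AugmentOp,
    PatchPair,
    apply_augment,
    assemble,
    extract_blocks,
    make_grid,
    sample_random_patch,
    standardize,
)
from advseg.types import Volume


class TestStandardize:
    def test_three_voxel_example(self):
        v = Volume(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        out = standardize(v)
        np.testing.assert_allclose(out.data.ravel(), [-1.0, 0.0, 1.0], atol=1e-6)

    def test_zero_mean_unit_sample_std(self, rng):
        v = Volume(rng.gamma(2.0, 3.0, (9, 8, 7)))
        out = standardize(v)
        assert abs(out.data.mean()) < 1e-5
        assert abs(out.data.std(ddof=1) - 1.0) < 1e-5
        assert out.shape == v.shape
        assert out.spacing == v.spacing

    def test_idempotent(self, rng):
        v = Volume(rng.normal(40.0, 7.0, (6, 6, 6)))
        once = standardize(v)
        twice = standardize(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-5)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(Volume(np.full((4, 4, 4), 3.0)))


class TestRandomPatch:
    def test_exact_fit_forces_origin_zero(self, rng):
        v = rng.normal(size=(16, 16, 16))
        pair = sample_random_patch(v, np.zeros_like(v, dtype=int), 16, rng)
        assert pair.origin == (0, 0, 0)
        np.testing.assert_array_equal(pair.image, v)

    def test_label_block_cut_at_same_offsets(self, rng):
        v = rng.normal(size=(20, 24, 30))
        lab = (v > 0).astype(np.int16)
        pair = sample_random_patch(v, lab, 8, rng)
        o = pair.origin
        np.testing.assert_array_equal(
            pair.labels, lab[o[0] : o[0] + 8, o[1] : o[1] + 8, o[2] : o[2] + 8]
        )

    def test_undersized_volume_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller"):
            sample_random_patch(np.zeros((32, 32, 32)), np.zeros((32, 32, 32), int), 64, rng)

    def test_origins_uniform_chi_square(self):
        # block offsets drawn independently per axis, uniform on [0, dim-patch]
        rng = np.random.default_rng(0)
        vol = np.zeros((128, 128, 128), dtype=np.uint8)
        lab = vol
        n_draws, patch = 4000, 64
        origins = np.array(
            [sample_random_patch(vol, lab, patch, rng).origin for _ in range(n_draws)]
        )
        for axis in range(3):
            counts = np.bincount(origins[:, axis], minlength=65)
            assert counts.size == 65  # no origin beyond dim - patch
            p = stats.chisquare(counts).pvalue
            assert p > 0.01


def _rot90_oracle(block: np.ndarray) -> np.ndarray:
    """Brute-force single quarter-turn of the axial plane by index loops."""
    d, h, w = block.shape
    out = np.empty((d, w, h), dtype=block.dtype)
    for y in range(w):
        for x in range(h):
            out[:, y, x] = block[:, x, w - 1 - y]
    return out


class TestAugment:
    def test_matches_bruteforce_permutation(self, rng):
        block = rng.integers(0, 1000, (4, 5, 5))
        for op in ALL_AUGMENTS:
            expect = block[::-1] if op.flip else block
            for _ in range(op.rot_quarters):
                expect = _rot90_oracle(expect)
            np.testing.assert_array_equal(op.apply(block), expect)

    def test_identity_op(self, rng):
        block = rng.normal(size=(4, 4, 4))
        np.testing.assert_array_equal(AugmentOp(0, False).apply(block), block)

    def test_quarter_turn_has_order_four(self, rng):
        block = rng.normal(size=(3, 6, 6))
        op = AugmentOp(1, False)
        out = block
        for _ in range(4):
            out = op.apply(out)
        np.testing.assert_array_equal(out, block)

    def test_group_closure_and_inverses(self, rng):
        block = rng.integers(0, 100, (4, 4, 4))
        for a in ALL_AUGMENTS:
            inv = a.inverse()
            assert inv in ALL_AUGMENTS
            np.testing.assert_array_equal(inv.apply(a.apply(block)), block)
            for b in ALL_AUGMENTS:
                composed = a.compose(b)
                assert composed in ALL_AUGMENTS
                np.testing.assert_array_equal(
                    a.apply(b.apply(block)), composed.apply(block)
                )

    def test_labels_move_with_image_and_multiset_preserved(self, rng):
        img = rng.normal(size=(4, 4, 4))
        lab = rng.integers(0, 3, (4, 4, 4))
        pair = PatchPair(image=img, labels=lab, origin=(0, 0, 0))
        for op in ALL_AUGMENTS:
            out = apply_augment(pair, op)
            # identical spatial map: co-located voxels stay co-located
            np.testing.assert_array_equal(out.labels, op.apply(lab))
            np.testing.assert_array_equal(out.image, op.apply(img))
            assert sorted(out.labels.ravel()) == sorted(lab.ravel())


def _coverage_bruteforce(shape, grid):
    mask = np.zeros(shape, dtype=np.int32)
    for origin in grid.origins:
        sl = tuple(slice(o, o + grid.patch_size) for o in origin)
        mask[sl] += 1
    return mask


class TestMakeGrid:
    def test_clamped_final_origin_example(self):
        grid = make_grid((100, 100, 100), 64, 32)
        per_axis = sorted({o[0] for o in grid.origins})
        assert per_axis == [0, 32, 36]

    def test_single_block_when_exact(self):
        grid = make_grid((64, 64, 64), 64, 17)
        assert grid.origins == ((0, 0, 0),)

    def test_perfect_tiling_no_overlap(self):
        grid = make_grid((128, 128, 128), 64, 64)
        assert len(grid.origins) == 8
        mask = _coverage_bruteforce((128, 128, 128), grid)
        assert (mask == 1).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        dims=st.tuples(*[st.integers(6, 40)] * 3),
        patch=st.integers(2, 6),
        data=st.data(),
    )
    def test_full_coverage_property(self, dims, patch, data):
        stride = data.draw(st.integers(1, patch))
        grid = make_grid(dims, patch, stride)
        assert (_coverage_bruteforce(dims, grid) >= 1).all()

    def test_undersized_rejected(self):
        with pytest.raises(ValueError):
            make_grid((32, 32, 32), 64, 32)


class TestAssemble:
    def test_constant_blocks(self):
        grid = make_grid((10, 10, 10), 6, 4)
        block = np.tile(np.array([0.2, 0.3, 0.5])[:, None, None, None], (1, 6, 6, 6))
        out = assemble([block.copy() for _ in grid.origins], grid, (10, 10, 10))
        np.testing.assert_allclose(out, np.tile(
            np.array([0.2, 0.3, 0.5])[:, None, None, None], (1, 10, 10, 10)
        ), atol=1e-7)

    def test_exact_reconstruction_of_known_map(self, rng):
        # cutting a full-volume map into overlapping grid blocks and
        # averaging them back is exact, because overlapping values agree
        shape = (20, 14, 17)
        probs = rng.dirichlet([1, 1, 1], shape).transpose(3, 0, 1, 2)
        grid = make_grid(shape, 8, 5)
        blocks = extract_blocks(probs, grid)
        out = assemble(blocks, grid, shape)
        np.testing.assert_allclose(out, probs, atol=1e-6)

    def test_two_block_overlap_mean(self):
        grid = make_grid((4, 4, 7), 4, 3)
        assert len(grid.origins) == 2
        b1 = np.zeros((3, 4, 4, 4)); b1[0] = 1.0
        b2 = np.zeros((3, 4, 4, 4)); b2[1] = 1.0
        out = assemble([b1, b2], grid, (4, 4, 7))
        np.testing.assert_allclose(out[:, 0, 0, 3], [0.5, 0.5, 0.0])
        np.testing.assert_allclose(out[:, 0, 0, 0], [1.0, 0.0, 0.0])
        np.testing.assert_allclose(out[:, 0, 0, 6], [0.0, 1.0, 0.0])

    def test_simplex_preserved(self, rng):
        shape = (9, 9, 9)
        grid = make_grid(shape, 4, 3)
        blocks = [
            rng.dirichlet([1, 1, 1], (4, 4, 4)).transpose(3, 0, 1, 2)
            for _ in grid.origins
        ]
        out = assemble(blocks, grid, shape)
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-6)
        assert (out >= 0).all()

    def test_block_count_mismatch(self):
        grid = make_grid((8, 8, 8), 4, 4)
        with pytest.raises(ValueError, match="blocks"):
            assemble([np.zeros((3, 4, 4, 4))], grid, (8, 8, 8))
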