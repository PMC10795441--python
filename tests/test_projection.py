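"""Ray-sum projection, joint 8-bit windowing, tiling, dataset assembly."""

import numpy as np
import pytest

from bonesup import phantom, projection
from bonesup.errors import ConfigurationError, DegenerateWindowError, SizeError
from bonesup.projection import (
    ImageDataset,
    ProjectionGeometry,
    ProjectionImage,
    build_dataset,
    normalize_pair,
    normalize_to_8bit,
    project_drr,
    reassemble,
    tile_3x3,
)


def _volume(voxels, voxel_size=0.03):
    shape = voxels.shape
    pop = phantom.default_population(shape, voxel_size)
    params = phantom.sample_phantom_params(pop, seed=0)
    zeros = np.zeros(shape, dtype=bool)
    return phantom.PhantomVolume(
        voxels=voxels, voxel_size=voxel_size, bone_mask=zeros,
        lung_mask=zeros, tumor_mask=zeros, params=params,
    )


class TestProjectDrr:
    def test_zero_volume_zero_projection(self):
        img = project_drr(_volume(np.zeros((8, 8, 8))), ProjectionGeometry(45.0))
        assert np.all(img.pixels == 0)
        assert img.value_domain == "raw"

    def test_single_voxel_ray_sum(self):
        # one voxel of mu=1 /cm at 0.03 cm: the straight ray integrates to 0.03
        vox = np.zeros((3, 3, 3))
        vox[1, 1, 1] = 1.0
        img = project_drr(_volume(vox), ProjectionGeometry(0.0))
        assert img.pixels[1, 1] == pytest.approx(0.03)
        assert img.pixels.sum() == pytest.approx(0.03)

    def test_linearity(self, rng):
        a = rng.random((6, 6, 6))
        b = rng.random((6, 6, 6))
        g = ProjectionGeometry(40.0)
        pa = project_drr(_volume(a), g).pixels
        pb = project_drr(_volume(b), g).pixels
        pab = project_drr(_volume(a + b), g).pixels
        np.testing.assert_allclose(pa + pb, pab, atol=1e-10)

    def test_zero_angle_is_exact_axis_sum(self, small_pair):
        img = project_drr(small_pair.with_bone, ProjectionGeometry(0.0))
        expected = small_pair.with_bone.voxels.sum(axis=1) * small_pair.with_bone.voxel_size
        assert np.array_equal(img.pixels, expected)

    def test_bone_shadow_property_axis_aligned(self, small_pair):
        # rays along y at 0 degrees: exact bone-ray membership is computable
        g = ProjectionGeometry(0.0)
        pw = project_drr(small_pair.with_bone, g).pixels
        pwo = project_drr(small_pair.without_bone, g).pixels
        bone_ray = small_pair.with_bone.bone_mask.any(axis=1)
        assert np.array_equal(pw[~bone_ray], pwo[~bone_ray])
        assert np.all(pw[bone_ray] > pwo[bone_ray])

    def test_invalid_angle_rejected(self):
        with pytest.raises(ConfigurationError):
            ProjectionGeometry(180.0)


class TestNormalize:
    def _raw(self, pixels):
        return ProjectionImage(pixels=np.asarray(pixels, float), value_domain="raw",
                               angle_deg=0.0, domain_tag="with_bone")

    def test_constant_with_explicit_window(self):
        out = normalize_to_8bit(self._raw(np.full((4, 4), 0.5)), window=(0.0, 1.0))
        assert np.all(out.pixels == 128)  # 0.5 -> 127.5, rounded half-up

    def test_binary_maps_to_extremes(self):
        out = normalize_to_8bit(self._raw([[0.0, 1.0]]), window=(0.0, 1.0))
        assert out.pixels.tolist() == [[0, 255]]

    def test_degenerate_window_rejected(self):
        with pytest.raises(DegenerateWindowError):
            normalize_to_8bit(self._raw(np.full((4, 4), 2.0)), window=(1.0, 1.0))

    def test_shared_window_preserves_raw_ordering(self, rng):
        for _ in range(10):
            a = rng.random((12, 12)) * 3
            b = a - rng.random((12, 12))  # everywhere <= a, like a bone-free pair
            b[b < 0] = 0.0
            ia, ib = normalize_pair(self._raw(a), self._raw(b))
            assert np.all(ia.pixels.astype(int) >= ib.pixels.astype(int))


class TestTiling:
    def test_nine_3x3_tiles_roundtrip(self):
        img = ProjectionImage(
            pixels=np.arange(81, dtype=np.uint8).reshape(9, 9), value_domain="8bit",
            angle_deg=0.0, domain_tag="with_bone",
        )
        grid = tile_3x3(img)
        assert [t.pixels.shape for t in grid.tiles] == [(3, 3)] * 9
        assert [t.tile_index for t in grid.tiles] == list(range(9))
        assert np.array_equal(reassemble(grid), img.pixels)

    def test_512_remainder_rule(self):
        img = ProjectionImage(pixels=np.zeros((512, 512), np.uint8), value_domain="8bit",
                              angle_deg=0.0, domain_tag="with_bone")
        grid = tile_3x3(img)
        heights = [grid.tiles[3 * i].pixels.shape[0] for i in range(3)]
        widths = [grid.tiles[j].pixels.shape[1] for j in range(3)]
        assert heights == [170, 170, 172]
        assert widths == [170, 170, 172]

    def test_random_roundtrip_bit_exact(self, rng):
        pix = rng.integers(0, 256, size=(100, 100)).astype(np.uint8)
        img = ProjectionImage(pixels=pix, value_domain="8bit", angle_deg=0.0,
                              domain_tag="with_bone")
        assert np.array_equal(reassemble(tile_3x3(img)), pix)

    def test_too_small_rejected(self):
        img = ProjectionImage(pixels=np.zeros((2, 5), np.uint8), value_domain="8bit",
                              angle_deg=0.0, domain_tag="with_bone")
        with pytest.raises(SizeError):
            tile_3x3(img)


@pytest.fixture(scope="module")
def ds() -> ImageDataset:
    return build_dataset(n_phantoms=4, angles=(40.0, 45.0, 50.0), test_fraction=0.25,
                         seed=11, grid_shape=(48, 48, 48))


class TestBuildDataset:

    def test_counts(self, ds):
        # n_phantoms x angles x 9 tiles per domain (56 x 3 x 9 = 1512 at study scale)
        assert len(ds.domain_X) == 4 * 3 * 9
        assert len(ds.domain_Y) == 4 * 3 * 9

    def test_split_hygiene(self, ds):
        for recs in (ds.domain_X, ds.domain_Y):
            for r in recs:
                assert r.split == ds.split[r.phantom_id]
        assert set(ds.split.values()) == {"train", "test"}

    def test_paired_test_set_aligned(self, ds):
        pairs = ds.test_pairs()
        assert len(pairs) == 1 * 3 * 9
        for x, y in pairs:
            assert x.key() == y.key()
            assert x.domain == "with_bone" and y.domain == "without_bone"

    def test_two_phantoms_half_split(self):
        ds = build_dataset(n_phantoms=2, angles=(45.0,), test_fraction=0.5, seed=0,
                           grid_shape=(48, 48, 48))
        assert sorted(ds.split.values()) == ["test", "train"]

    def test_same_seed_same_manifest(self):
        kw = dict(n_phantoms=2, angles=(45.0,), test_fraction=0.5, seed=3,
                  grid_shape=(48, 48, 48))
        assert build_dataset(**kw).manifest == build_dataset(**kw).manifest

    def test_empty_split_rejected(self):
        with pytest.raises(ConfigurationError):
            build_dataset(n_phantoms=4, angles=(45.0,), test_fraction=0.0, seed=0,
                          grid_shape=(48, 48, 48))

    def test_dataset_png_roundtrip(self, tmp_path):
        ds = build_dataset(n_phantoms=2, angles=(45.0,), test_fraction=0.5, seed=1,
                           grid_shape=(48, 48, 48), out_dir=tmp_path)
        assert (tmp_path / "manifest.json").exists()
        pngs = list(tmp_path.rglob("*.png"))
        assert len(pngs) == len(ds.domain_X) + len(ds.domain_Y)
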