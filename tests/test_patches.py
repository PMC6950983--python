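"""Grid/boundary patch geometry, foreground filtering, split, augmentation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleiseg import (AugmentConfig, PatchGridConfig, PatchRecord, augment,
                       grid_patches, random_patches, split_train_val)


def _offsets(patches):
    return sorted({(p.row0, p.col0) for p in patches})


def test_exact_patch_image_single_patch():
    g = grid_patches(np.zeros((256, 256)), np.zeros((256, 256)))
    assert _offsets(g) == [(0, 0)]
    assert g[0].origin == "grid" and not g[0].was_padded


def test_512_gives_four_grid_patches():
    g = grid_patches(np.zeros((512, 512)), np.zeros((512, 512)))
    assert _offsets(g) == [(0, 0), (0, 256), (256, 0), (256, 256)]
    assert all(p.origin == "grid" for p in g)


def test_300_gives_boundary_recrops_at_44():
    g = grid_patches(np.zeros((300, 300)), np.zeros((300, 300)))
    assert _offsets(g) == [(0, 0), (0, 44), (44, 0), (44, 44)]
    for p in g:
        # re-crops end exactly at the image boundary
        assert p.row0 + 256 in (256, 300) and p.col0 + 256 in (256, 300)
    origins = {(p.row0, p.col0): p.origin for p in g}
    assert origins[(0, 0)] == "grid"
    assert origins[(44, 44)] == "boundary"


def test_small_image_zero_padded():
    img = np.full((100, 100), 0.5)
    g = grid_patches(img, np.ones((100, 100)))
    assert len(g) == 1
    p = g[0]
    assert p.was_padded and p.image_patch.shape == (256, 256)
    assert (p.image_patch[:100, :100] == 0.5).all()
    assert (p.image_patch[100:, :] == 0).all() and (p.image_patch[:, 100:] == 0).all()
    assert p.mask_patch[:100, :100].all() and p.mask_patch[100:, :].sum() == 0


def test_empty_image_rejected():
    with pytest.raises(ValueError):
        grid_patches(np.zeros((0, 0)), np.zeros((0, 0)))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(256, 1024), st.integers(256, 1024))
def test_coverage_and_count_for_random_sizes(h, w):
    img = np.zeros((h, w))
    g = grid_patches(img, img)
    assert len(g) == int(np.ceil(h / 256) * np.ceil(w / 256))
    covered = np.zeros((h, w), dtype=bool)
    for p in g:
        covered[p.row0:p.row0 + 256, p.col0:p.col0 + 256] = True
    assert covered.all()


def test_random_patches_all_background_empty():
    img = np.zeros((300, 300))
    assert random_patches(img, np.zeros_like(img)) == []


def test_random_patches_all_foreground_full_quota():
    img = np.zeros((300, 300))
    cfg = PatchGridConfig(n_random_patches_per_image=4, seed=1)
    got = random_patches(img, np.ones_like(img), cfg)
    assert len(got) == 4
    assert all(p.origin == "random" for p in got)


def test_fg_ratio_exactly_threshold_is_rejected():
    """fg/bg == 0.4 exactly must fail the strictly-greater filter."""
    ps = 14  # 196 pixels: fg = 56, bg = 140 gives exactly 56/140 = 0.4
    n_fg = 56
    assert n_fg / (ps * ps - n_fg) == 0.4
    cfg = PatchGridConfig(patch_size=ps, grid_dx=ps, grid_dy=ps,
                          n_random_patches_per_image=2, seed=0)
    mask = np.zeros((ps, ps))
    mask.ravel()[:n_fg] = 1
    assert random_patches(np.zeros((ps, ps)), mask, cfg) == []
    # one more foreground pixel crosses the threshold
    mask.ravel()[n_fg] = 1
    assert len(random_patches(np.zeros((ps, ps)), mask, cfg)) == 2


def test_random_patches_small_image_returns_empty():
    assert random_patches(np.zeros((100, 100)), np.zeros((100, 100))) == []


def test_random_patches_deterministic_under_seed():
    rng = np.random.default_rng(3)
    img = rng.random((400, 400))
    mask = (rng.random((400, 400)) < 0.5).astype(np.uint8)
    cfg = PatchGridConfig(n_random_patches_per_image=3, seed=7)
    a = random_patches(img, mask, cfg, "img1")
    b = random_patches(img, mask, cfg, "img1")
    assert [(p.row0, p.col0) for p in a] == [(p.row0, p.col0) for p in b]


def _dummy_patches(n):
    z = np.zeros((8, 8))
    return [PatchRecord(f"s{i}", 0, 0, z, z.astype(np.uint8)) for i in range(n)]


def test_split_is_8_to_2():
    train, val = split_train_val(_dummy_patches(10))
    assert len(train) == 8 and len(val) == 2


@pytest.mark.parametrize("n", [1, 5, 9, 37, 100])
def test_split_partition_and_determinism(n):
    patches = _dummy_patches(n)
    cfg = PatchGridConfig(seed=5)
    t1, v1 = split_train_val(patches, cfg)
    t2, v2 = split_train_val(patches, cfg)
    assert [p.source_id for p in t1] == [p.source_id for p in t2]
    assert [p.source_id for p in v1] == [p.source_id for p in v2]
    assert len(t1) == int(np.floor(0.8 * n + 0.5))
    ids = sorted(p.source_id for p in t1 + v1)
    assert ids == sorted(p.source_id for p in patches)


def test_split_empty_rejected():
    with pytest.raises(ValueError):
        split_train_val([])


def _coord_patch():
    """A patch whose pixel values encode their own coordinates."""
    yy, xx = np.mgrid[0:32, 0:32]
    img = (yy * 32 + xx) / (32 * 32)
    mask = ((yy * 32 + xx) % 3 == 0).astype(np.uint8)
    return PatchRecord("c", 0, 0, img, mask)


def test_augment_identity_when_all_probabilities_zero():
    p = _coord_patch()
    out = augment(p, seed=0, aug_config=AugmentConfig.identity())
    assert (out.image_patch == p.image_patch).all()
    assert (out.mask_patch == p.mask_patch).all()


def test_augment_geometric_transform_identical_for_image_and_mask():
    cfg = AugmentConfig(p_blur=0, p_contrast=0, p_saturation=0, p_hue=0,
                        p_flip=1.0, p_rot90=1.0)
    p = _coord_patch()
    # mask := image coordinates, so both must transform the same way
    coords = (p.image_patch * 32 * 32).astype(np.int32)
    rec = PatchRecord("c", 0, 0, p.image_patch, coords)
    out = augment(rec, seed=13, aug_config=cfg)
    assert ((out.image_patch * 32 * 32).round().astype(np.int32)
            == out.mask_patch).all()


def test_augment_deterministic_and_clipped():
    p = _coord_patch()
    cfg = AugmentConfig(p_blur=1.0, p_contrast=1.0, p_saturation=1.0,
                        p_hue=1.0, p_flip=1.0, p_rot90=1.0)
    a = augment(p, seed=21, aug_config=cfg)
    b = augment(p, seed=21, aug_config=cfg)
    assert (a.image_patch == b.image_patch).all()
    assert (a.mask_patch == b.mask_patch).all()
    assert a.image_patch.min() >= 0 and a.image_patch.max() <= 1
    assert a.image_patch.shape == p.image_patch.shape


def test_photometric_ops_leave_mask_untouched():
    cfg = AugmentConfig(p_blur=1.0, p_contrast=1.0, p_saturation=1.0,
                        p_hue=1.0, p_flip=0, p_rot90=0)
    p = _coord_patch()
    out = augment(p, seed=2, aug_config=cfg)
    assert (out.mask_patch == p.mask_patch).all()
    assert not (out.image_patch == p.image_patch).all()


def test_grid_config_validation():
    with pytest.raises(ValueError):
        PatchGridConfig(patch_size=0)
    with pytest.raises(ValueError):
        PatchGridConfig(split_ratio=1.0)
    with pytest.raises(ValueError):
        PatchGridConfig(grid_dx=128)
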