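"""The 65-feature registry and each feature family against closed-form or
enumeration oracles."""

import numpy as np
import pytest

from speckletex.features import (
    FEATURE_GROUPS,
    FEATURE_REGISTRY,
    FeatureConfig,
    FeatureVector,
    cooccurrence_features,
    extract_features,
    feature_matrix,
    granulometry_features,
    local_stat_features,
    moment_features,
    wavelet_features,
)
from speckletex.types import ImageStack, RoiMask, ValidationError


def full_roi(shape):
    return RoiMask(mask=np.ones(shape, bool))


# ------------------------------------------------------------- registry


def test_registry_has_65_features_in_the_documented_groups():
    sizes = {g: len(names) for g, names in FEATURE_GROUPS.items()}
    assert sizes == {
        "local_stats": 12,
        "moments": 2,
        "cooccurrence": 12,
        "granulometry": 21,
        "wavelet": 18,
    }
    assert len(FEATURE_REGISTRY) == 65
    assert len(set(FEATURE_REGISTRY)) == 65


def test_feature_vector_validates_length_and_finiteness():
    with pytest.raises(ValidationError):
        FeatureVector(values=np.zeros(64))
    bad = np.zeros(65)
    bad[3] = np.nan
    with pytest.raises(ValidationError, match="non-finite"):
        FeatureVector(values=bad)


# ------------------------------------------------------------- local stats


def test_constant_stack_gives_zero_local_maps(constant_stack):
    vals = local_stat_features(constant_stack, full_roi(constant_stack.shape))
    # mean/median/std of each all-zero map are 0; map entropy of a point mass is 0
    assert np.allclose(vals, 0.0)


def test_checkerboard_normalized_mean_range_is_one():
    zz, yy, xx = np.indices((16, 16, 16))
    cb = (((zz + yy + xx) % 2) * 255).astype(np.uint8)
    st = ImageStack(voxels=cb)
    vals = local_stat_features(st, full_roi((16, 16, 16)))
    named = dict(zip(FEATURE_GROUPS["local_stats"], vals))
    assert named["local_range_mean"] == pytest.approx(1.0)
    assert named["local_range_median"] == pytest.approx(1.0)


def test_local_stats_reject_too_small_stacks():
    st = ImageStack(voxels=np.zeros((3, 3, 3), np.uint8))
    with pytest.raises(ValidationError):
        local_stat_features(st, full_roi((3, 3, 3)))


# ------------------------------------------------------------- moments


def test_two_point_distribution_moments_match_closed_form():
    v = np.zeros((16, 16, 16), np.uint8)
    v[:8] = 255  # equal-mass two-point distribution
    st = ImageStack(voxels=v)
    skew, kurt = moment_features(st, full_roi(v.shape))
    assert skew == pytest.approx(0.0, abs=1e-12)
    assert kurt == pytest.approx(1.0, abs=1e-12)


def test_gaussian_sample_moments_near_normal_values():
    rng = np.random.default_rng(0)
    v = np.clip(np.rint(128 + 20 * rng.standard_normal((47, 47, 47))), 0, 255).astype(np.uint8)
    st = ImageStack(voxels=v)
    skew, kurt = moment_features(st, full_roi(v.shape))
    assert abs(skew) < 0.05
    assert abs(kurt - 3.0) < 0.1


def test_constant_roi_moments_are_zero_by_convention(constant_stack):
    with pytest.warns(UserWarning):
        skew, kurt = moment_features(constant_stack, full_roi(constant_stack.shape))
    assert (skew, kurt) == (0.0, 0.0)


# ------------------------------------------------------------- co-occurrence


def test_constant_roi_cooccurrence_degenerate_values(constant_stack):
    vals = cooccurrence_features(constant_stack, full_roi(constant_stack.shape))
    for ax in range(3):
        contrast, corr, energy, homog = vals[4 * ax: 4 * ax + 4]
        assert contrast == 0.0
        assert corr == 1.0  # convention for a single-cell matrix
        assert energy == 1.0
        assert homog == 1.0


def test_stripes_maximize_contrast_along_their_axis():
    x = np.arange(40)
    stripe = ((x // 5) % 2 * 255).astype(np.uint8)
    st = ImageStack(voxels=np.broadcast_to(stripe[None, None, :], (20, 40, 40)).copy())
    vals = cooccurrence_features(st, full_roi((20, 40, 40)), offset_vox=5, levels=8)
    named = dict(zip(FEATURE_GROUPS["cooccurrence"], vals))
    assert named["glcm_x_contrast"] == pytest.approx((8 - 1) ** 2)
    assert named["glcm_z_contrast"] == 0.0
    assert named["glcm_y_contrast"] == 0.0


def test_uniform_noise_cooccurrence_statistics_are_iid_like():
    rng = np.random.default_rng(1)
    v = rng.integers(0, 256, (40, 40, 40)).astype(np.uint8)
    st = ImageStack(voxels=v)
    vals = cooccurrence_features(st, full_roi(v.shape), offset_vox=5, levels=8)
    named = dict(zip(FEATURE_GROUPS["cooccurrence"], vals))
    for ax in ("x", "y", "z"):
        assert named[f"glcm_{ax}_energy"] == pytest.approx(1 / 64, rel=0.05)
        assert abs(named[f"glcm_{ax}_correlation"]) < 0.02


def test_cooccurrence_requires_extent_beyond_offset():
    st = ImageStack(voxels=np.zeros((4, 16, 16), np.uint8))
    with pytest.raises(ValidationError, match="z"):
        cooccurrence_features(st, full_roi((4, 16, 16)), offset_vox=5)


# ------------------------------------------------------------- granulometry


def place_particle(v, size, start=(2, 2, 2)):
    """Hand-place a connected dark particle of `size` voxels in a bright image."""
    z, y, x = start
    placed = 0
    for i in range(size):
        v[z, y, x + i] = 0
        placed += 1
    return placed


def test_single_particle_lands_in_its_bin():
    v = np.full((32, 32, 32), 255, np.uint8)
    place_particle(v, 3)  # size 3 -> bin (2, 4] -> index 1
    st = ImageStack(voxels=v)
    vals = granulometry_features(st, full_roi(v.shape))
    h12, h6, h3 = vals[:12], vals[12:18], vals[18:]
    expect12 = np.zeros(12)
    expect12[1] = 1.0
    assert np.allclose(h12, expect12)
    assert np.allclose(h6, [1, 0, 0, 0, 0, 0])
    assert np.allclose(h3, [1, 0, 0])


def test_two_particles_in_neighboring_bins():
    v = np.full((32, 32, 32), 255, np.uint8)
    place_particle(v, 1, start=(2, 2, 2))  # size 1 -> bin 0
    place_particle(v, 3, start=(10, 10, 2))  # size 3 -> bin 1
    st = ImageStack(voxels=v)
    vals = granulometry_features(st, full_roi(v.shape))
    assert np.allclose(vals[:12], [0.5, 0.5] + [0] * 10)
    assert np.allclose(vals[12:18], [1, 0, 0, 0, 0, 0])


def test_all_white_roi_has_no_particles(constant_stack):
    vals = granulometry_features(constant_stack, full_roi(constant_stack.shape))
    assert np.allclose(vals, 0.0)


def test_custom_bin_edges_validated():
    v = np.full((16, 16, 16), 255, np.uint8)
    st = ImageStack(voxels=v)
    with pytest.raises(ValidationError):
        granulometry_features(st, full_roi(v.shape), bin_edges_12=[1, 2, 3])


# ------------------------------------------------------------- wavelets


def test_constant_stack_has_zero_wavelet_features(constant_stack):
    vals = wavelet_features(constant_stack, full_roi(constant_stack.shape))
    assert np.allclose(vals, 0.0, atol=1e-10)


def test_variation_along_x_drives_the_x_direction_bands():
    # broadband random profile along x, constant along y: all x-bands carry
    # energy at every scale, all y-bands stay at zero
    profile = np.random.default_rng(2).integers(0, 256, 32).astype(np.uint8)
    st = ImageStack(voxels=np.broadcast_to(profile[None, None, :], (8, 32, 32)).copy())
    vals = wavelet_features(st, full_roi((8, 32, 32)))
    named = dict(zip(FEATURE_GROUPS["wavelet"], vals))
    for s in (1, 2, 3):
        assert named[f"dwt_x_scale{s}_mean"] > 10 * named[f"dwt_y_scale{s}_mean"]


def test_rotating_the_image_swaps_x_and_y_bands():
    rng = np.random.default_rng(3)
    img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    st = ImageStack(voxels=np.repeat(img[None], 8, axis=0))
    rot = ImageStack(voxels=np.repeat(np.rot90(img)[None], 8, axis=0).copy())
    v0 = dict(zip(FEATURE_GROUPS["wavelet"], wavelet_features(st, full_roi(st.shape))))
    v1 = dict(zip(FEATURE_GROUPS["wavelet"], wavelet_features(rot, full_roi(rot.shape))))
    for s in (1, 2, 3):
        for stat in ("mean", "std"):
            a = v0[f"dwt_x_scale{s}_{stat}"]
            b = v1[f"dwt_y_scale{s}_{stat}"]
            assert a == pytest.approx(b, rel=0.05)


def test_wavelets_reject_too_small_plane():
    st = ImageStack(voxels=np.zeros((16, 4, 4), np.uint8))
    with pytest.raises(ValidationError):
        wavelet_features(st, RoiMask(mask=np.ones((16, 4, 4), bool)), n_scales=3)


# ------------------------------------------------------------- assembly


def test_extract_features_returns_65_finite_values(control_stack):
    from speckletex.pipeline import stack_to_features

    fv = stack_to_features(control_stack)
    assert fv.values.shape == (65,)
    assert np.all(np.isfinite(fv.values))


def test_extraction_is_deterministic(control_stack):
    from speckletex.preprocess import apply_crop, preprocess_stack
    from speckletex.roi import equalize_in_roi, mask_roi_auto

    body, rep = preprocess_stack(control_stack)
    body = apply_crop(body, rep.crop_box)
    roi = mask_roi_auto(body)
    eq = equalize_in_roi(body, roi)
    a = extract_features(eq, roi).values
    b = extract_features(eq, roi).values
    assert np.array_equal(a, b)


def test_whole_voxel_translation_leaves_features_unchanged():
    rng = np.random.default_rng(4)
    core = rng.integers(0, 256, (24, 24, 24)).astype(np.uint8)
    pad = np.zeros((40, 40, 40), np.uint8)
    pad[4:28, 4:28, 4:28] = core
    m0 = np.zeros((40, 40, 40), bool)
    m0[6:26, 6:26, 6:26] = True
    shifted = np.roll(pad, (5, 3, 2), axis=(0, 1, 2))
    m1 = np.roll(m0, (5, 3, 2), axis=(0, 1, 2))
    f0 = extract_features(ImageStack(voxels=pad), RoiMask(mask=m0)).values
    f1 = extract_features(ImageStack(voxels=shifted), RoiMask(mask=m1)).values
    assert np.allclose(f0, f1, atol=1e-9)


def test_degeneration_separates_many_features():
    """At least 10 of 65 features show |Cohen's d| > 1 between control and
    fully degenerated batches — the mechanism behind class separability."""
    from speckletex.phantom import PhantomSpec, generate_timecourse
    from speckletex.pipeline import stack_to_features

    base = PhantomSpec(shape=(48, 48, 48), seed=31, coverslip_amp=0.0)
    g0 = generate_timecourse(base, [0.0], 20)
    g1 = generate_timecourse(
        PhantomSpec(shape=(48, 48, 48), seed=32, coverslip_amp=0.0), [1.0], 20
    )
    F0 = np.array([stack_to_features(s, run_preprocess=False).values for s in g0])
    F1 = np.array([stack_to_features(s, run_preprocess=False).values for s in g1])
    pooled = np.sqrt((F0.var(axis=0, ddof=1) + F1.var(axis=0, ddof=1)) / 2)
    pooled[pooled == 0] = np.inf
    d = np.abs(F0.mean(axis=0) - F1.mean(axis=0)) / pooled
    assert (d > 1.0).sum() >= 10


def test_feature_matrix_bookkeeping():
    vecs = [FeatureVector(values=np.full(65, float(i))) for i in range(4)]
    df = feature_matrix(vecs, ["a", "a", "b", "b"], ["s0", "s1", "s0", "s1"], [0, 0, 1, 1])
    assert list(df.columns[:65]) == FEATURE_REGISTRY
    assert df.shape == (4, 68)
    with pytest.raises(ValidationError):
        feature_matrix(vecs, ["a"], ["s0"])
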