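import numpy as np
import pytest

from ichradiomics import features as F
from ichradiomics.cohort import PhantomSpec, generate_phantom
from ichradiomics.imaging import LABEL_ICH, RegionMask, VolumeGrid

from .conftest import ball_mask
from .oracles import naive_texture_features


def strip_roi(levels_1d):
    """DiscretisedROI holding a 1-D strip along axis 0."""
    lv = np.asarray(levels_1d, dtype=np.int32).reshape(-1, 1, 1)
    return F.DiscretisedROI(
        levels=lv, mask=lv > 0, ng=int(lv.max()), ng_effective=len(set(levels_1d)),
        bin_edges=np.arange(int(lv.max()) + 1, dtype=float),
    )


# ---------------------------------------------------------------------------
# catalogue


def test_catalogue_size_and_uniqueness():
    entries = F.build_catalogue()
    ids = F.catalogue_ids()
    assert len(entries) == 754
    assert len(set(ids)) == 754
    # composition: 24 shape + 13 x 56 + 2 volumes
    assert len(F.SHAPE_NAMES) == 24
    assert len(F.PER_IMAGE_NAMES) == 56
    assert 24 + 13 * 56 + 2 == 754


def test_catalogue_errors_with_empty_sigmas():
    with pytest.raises(F.CatalogueError):
        F.build_catalogue(sigmas=[])


# ---------------------------------------------------------------------------
# discretisation


def test_discretise_constant_roi():
    data = np.full((3, 3, 3), 5.0)
    d = F.discretise_roi(data, np.ones((3, 3, 3), bool), ng=32)
    assert set(d.roi_levels.tolist()) == {1}
    assert d.ng_effective == 1


def test_discretise_unit_width_bins():
    data = np.arange(32, dtype=float).reshape(2, 4, 4)
    d = F.discretise_roi(data, np.ones((2, 4, 4), bool), ng=32)
    assert np.array_equal(np.sort(d.roi_levels), np.arange(1, 33))


def test_discretise_hand_example():
    data = np.array([10.0, 20.0, 30.0, 40.0]).reshape(4, 1, 1)
    d = F.discretise_roi(data, np.ones((4, 1, 1), bool), ng=2)
    assert d.roi_levels.tolist() == [1, 1, 2, 2]


def test_discretise_empty_roi():
    with pytest.raises(F.EmptyROIError):
        F.discretise_roi(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))


# ---------------------------------------------------------------------------
# first order


def test_first_order_constant():
    out = F.first_order_features(np.array([5.0, 5.0, 5.0]))
    assert out["variance"] == 0.0
    assert out["interquartile range"] == 0.0
    assert out["energy"] == 75.0
    assert out["entropy"] == 0.0
    assert out["uniformity"] == 1.0


def test_first_order_small_example():
    out = F.first_order_features(np.array([1.0, 2.0, 3.0, 4.0]))
    assert out["mean"] == 2.5
    assert out["energy"] == 30.0
    assert out["median"] == 2.5
    assert out["range"] == 3.0
    assert out["mean absolute deviation"] == 1.0


def test_kurtosis_is_pearson_convention():
    rng = np.random.default_rng(12)
    out = F.first_order_features(rng.standard_normal(100_000))
    assert abs(out["kurtosis"] - 3.0) < 0.1
    assert abs(out["skewness"]) < 0.05


def test_first_order_order_invariant():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(500)
    a = F.first_order_features(x)
    b = F.first_order_features(x[::-1].copy())
    for k in a:
        assert a[k] == pytest.approx(b[k], abs=1e-12)


# ---------------------------------------------------------------------------
# shape


def test_ball_sphericity_and_flatness():
    mask = ball_mask(20)
    out = F.shape_features(mask)
    assert 0.97 <= out["sphericity"] <= 1.005
    assert abs(out["flatness"] - 1.0) < 0.02
    # mesh volume close to (4/3) pi r^3
    expect_ml = 4.0 / 3.0 * np.pi * 20**3 / 1000.0
    assert out["mesh volume ml"] == pytest.approx(expect_ml, rel=0.03)


def test_box_axis_lengths():
    labels = np.zeros((44, 14, 14), dtype=int)
    labels[2:42, 2:12, 2:12] = 1
    out = F.shape_features(RegionMask(labels, (1, 1, 1)))
    lam1 = (40**2 - 1) / 12.0  # variance of a discrete uniform over 40 positions
    assert out["major axis length mm"] == pytest.approx(4 * np.sqrt(lam1), rel=1e-6)
    lam3 = (10**2 - 1) / 12.0
    expect_flat = np.sqrt(lam3 / lam1)
    assert out["flatness"] == pytest.approx(expect_flat, rel=1e-6)
    assert abs(out["flatness"] - 10 / 40) / (10 / 40) < 0.05


def test_single_voxel_degenerate():
    labels = np.zeros((5, 5, 5), dtype=int)
    labels[2, 2, 2] = 1
    with pytest.warns(UserWarning, match="degenerate"):
        out = F.shape_features(RegionMask(labels, (2, 2, 2)))
    assert out["voxel volume ml"] == pytest.approx(8.0 / 1000.0)
    assert out["flatness"] == 0.0
    assert out["elongation"] == 0.0


def test_shape_empty_roi():
    with pytest.raises(F.EmptyROIError):
        F.shape_features(RegionMask(np.zeros((4, 4, 4), dtype=int), (1, 1, 1)))


# ---------------------------------------------------------------------------
# GLCM


def test_glcm_single_level():
    d = strip_roi([1, 1, 1, 1])
    out = F.glcm_features(d)
    assert out["GLCM dissimilarity"] == 0.0
    assert out["GLCM entropy"] == 0.0
    assert out["GLCM energy"] == 1.0


def test_glcm_alternating_strip():
    # strip [1,2,1,2]: only offset (1,0,0) has pairs -> 3 adjacent (1,2) pairs
    d = strip_roi([1, 2, 1, 2])
    out = F.glcm_features(d)
    assert out["GLCM dissimilarity"] == pytest.approx(1.0)
    assert out["GLCM contrast"] == pytest.approx(1.0)


def test_glcm_uniform_matrix_entropy():
    p = np.full((4, 4), 1.0 / 16.0)
    out = F._glcm_features_one(p)
    assert out["GLCM entropy"] == pytest.approx(4.0)


def test_glcm_matrices_symmetric_normalised():
    rng = np.random.default_rng(2)
    lv = rng.integers(1, 5, (5, 5, 5)).astype(np.int32)
    d = F.DiscretisedROI(lv, lv > 0, 4, 4, np.arange(5.0))
    for m in F.glcm_matrices(d):
        assert m.sum() == pytest.approx(1.0)
        assert np.allclose(m, m.T)


# ---------------------------------------------------------------------------
# GLRLM


def test_glrlm_single_run():
    d = strip_roi([1, 1, 1, 1, 1, 1])
    mat = F.glrlm_matrix(d, (1, 0, 0))
    assert mat.shape == (1, 6)
    assert mat[0, 5] == 1.0
    out = F._glrlm_features_one(mat, 6)
    assert out["GLRLM run percentage"] == pytest.approx(1.0 / 6.0)


def test_glrlm_alternating_all_short():
    d = strip_roi([1, 2, 1, 2, 1, 2])
    mat = F.glrlm_matrix(d, (1, 0, 0))
    out = F._glrlm_features_one(mat, 6)
    assert out["GLRLM long run emphasis"] == pytest.approx(1.0)
    assert out["GLRLM short run emphasis"] == pytest.approx(1.0)


def test_glrlm_constant_cube_longer_runs():
    cube = np.ones((4, 4, 4), dtype=np.int32)
    d_const = F.DiscretisedROI(cube, cube > 0, 2, 1, np.arange(3.0))
    alt = np.indices((4, 4, 4)).sum(axis=0) % 2 + 1
    d_alt = F.DiscretisedROI(alt.astype(np.int32), alt > 0, 2, 2, np.arange(3.0))
    lre_const = F.glrlm_features(d_const)["GLRLM long run emphasis"]
    lre_alt = F.glrlm_features(d_alt)["GLRLM long run emphasis"]
    assert lre_const > lre_alt


# ---------------------------------------------------------------------------
# GLSZM


def test_glszm_single_zone():
    lv = np.ones((3, 3, 3), dtype=np.int32)
    d = F.DiscretisedROI(lv, lv > 0, 1, 1, np.arange(2.0))
    out = F.glszm_features(d)
    assert out["GLSZM zone percentage"] == pytest.approx(1.0 / 27.0)
    assert out["GLSZM small zone emphasis"] == pytest.approx(1.0 / 27.0**2)


def test_glszm_two_plates_hand_matrix():
    # two 2x2x1 plates of level 1 separated by a level-2 slab: 3 zones of 4
    lv = np.zeros((2, 2, 3), dtype=np.int32)
    lv[:, :, 0] = 1
    lv[:, :, 1] = 2
    lv[:, :, 2] = 1
    d = F.DiscretisedROI(lv, lv > 0, 2, 2, np.arange(3.0))
    mat = F.glszm_matrix(d)
    expect = np.zeros((2, 4))
    expect[0, 3] = 2.0  # two level-1 zones of size 4
    expect[1, 3] = 1.0  # one level-2 zone of size 4
    assert np.array_equal(mat, expect)


def test_glszm_singleton_small_zone_emphasis():
    # isolated voxels of distinct levels with gaps: every zone size 1
    lv = np.zeros((5, 5, 1), dtype=np.int32)
    lv[0, 0] = 1
    lv[0, 3] = 2
    lv[3, 0] = 3
    lv[3, 3] = 4
    d = F.DiscretisedROI(lv, lv > 0, 4, 4, np.arange(5.0))
    out = F.glszm_features(d)
    assert out["GLSZM small zone emphasis"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# NGTDM


def test_ngtdm_constant_roi():
    lv = np.ones((3, 3, 3), dtype=np.int32)
    d = F.DiscretisedROI(lv, lv > 0, 1, 1, np.arange(2.0))
    out = F.ngtdm_features(d)
    assert out["NGTDM complexity"] == 0.0
    assert out["NGTDM contrast"] == 0.0


def test_ngtdm_hand_table():
    # 3x3x1 grid, centre level 2 amid level 1:
    # s_2 = |2 - 1| = 1; s_1 = 4 corners x 1/3 + 4 edges x 1/5 = 32/15
    lv = np.ones((3, 3, 1), dtype=np.int32)
    lv[1, 1, 0] = 2
    d = F.DiscretisedROI(lv, lv > 0, 2, 2, np.arange(3.0))
    n_i, p_i, s_i = F.ngtdm_table(d)
    assert n_i.tolist() == [8.0, 1.0]
    assert p_i.tolist() == pytest.approx([8 / 9, 1 / 9])
    assert s_i[0] == pytest.approx(32.0 / 15.0)
    assert s_i[1] == pytest.approx(1.0)


def test_ngtdm_coarseness_decreases_with_frequency():
    idx = np.indices((8, 8, 8)).sum(axis=0)
    fine = (idx % 2 + 1).astype(np.int32)           # voxel-wise checkerboard
    coarse = ((idx // 4) % 2 + 1).astype(np.int32)  # 4-voxel blocks
    d_fine = F.DiscretisedROI(fine, fine > 0, 2, 2, np.arange(3.0))
    d_coarse = F.DiscretisedROI(coarse, coarse > 0, 2, 2, np.arange(3.0))
    c_fine = F.ngtdm_features(d_fine)["NGTDM coarseness"]
    c_coarse = F.ngtdm_features(d_coarse)["NGTDM coarseness"]
    assert c_coarse > c_fine


# ---------------------------------------------------------------------------
# texture oracle (spot check; the 100-seed sweep is in test_acceptance)


def test_texture_matches_naive_oracle_spot():
    rng = np.random.default_rng(0)
    lv = rng.integers(1, 5, (6, 6, 6)).astype(np.int32)
    lv[rng.random((6, 6, 6)) < 0.25] = 0  # carve an irregular ROI
    d = F.DiscretisedROI(lv, lv > 0, 4, int(len(np.unique(lv[lv > 0]))), np.arange(5.0))
    ours = F.texture_features(d)
    ref = naive_texture_features(lv, 4)
    for k, v in ref.items():
        assert ours[k] == pytest.approx(v, abs=1e-10), k


# ---------------------------------------------------------------------------
# extraction


def test_extract_subject_754_and_deterministic(phantom):
    vol, mask = phantom
    values, meta = F.extract_subject(vol, mask, subject_id="s1", clinical={"age": 70})
    assert len(values) == 754
    assert list(values) == F.catalogue_ids()
    assert all(np.isfinite(v) for v in values.values())
    assert meta["age"] == 70
    values2, _ = F.extract_subject(vol, mask, subject_id="s1")
    assert values == values2


def test_extract_subject_empty_ich():
    vol = VolumeGrid(np.zeros((8, 8, 8)), (1, 1, 1))
    mask = RegionMask(np.zeros((8, 8, 8), dtype=int), (1, 1, 1))
    with pytest.raises(F.SubjectExcluded):
        F.extract_subject(vol, mask)


def test_extract_subject_empty_phe_is_zero():
    spec = PhantomSpec(oedema_thickness_mm=0.0, seed=3)
    vol, mask = generate_phantom(spec)
    assert not np.any(mask.labels == 3)
    values, _ = F.extract_subject(vol, mask)
    assert values["perihaematomal oedema volume ml"] == 0.0
    assert values["intraventricular haemorrhage volume ml"] > 0.0


def test_extract_volumes_match_mask(thin_phantom):
    from ichradiomics.imaging import LABEL_IVH, LABEL_PHE, region_volume_ml

    vol, mask = thin_phantom
    values, _ = F.extract_subject(vol, mask, presampled=True)
    assert values["perihaematomal oedema volume ml"] == pytest.approx(
        region_volume_ml(mask, LABEL_PHE)
    )
    assert values["intraventricular haemorrhage volume ml"] == pytest.approx(
        region_volume_ml(mask, LABEL_IVH)
    )
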