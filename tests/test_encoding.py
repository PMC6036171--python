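import numpy as np
import pytest

from affectstates.encoding import (compare_encodings, group_maps,
                                   haufe_transform, subject_encoding)
from conftest import make_betas, planted_group


def test_haufe_identity_covariance_recovers_weights(rng):
    x = rng.standard_normal((5000, 12))
    w = rng.standard_normal(12)
    enc = haufe_transform(w, x)
    cos = enc @ w / np.linalg.norm(enc) / np.linalg.norm(w)
    assert cos > 0.97


def test_haufe_direction_invariant_to_feature_scaling(rng):
    x = rng.standard_normal((300, 8))
    w = rng.standard_normal(8)
    enc = haufe_transform(w, x)
    enc_scaled = haufe_transform(w, 3.0 * x)
    cos = (enc @ enc_scaled) / np.linalg.norm(enc) / np.linalg.norm(enc_scaled)
    assert cos == pytest.approx(1.0, abs=1e-10)


def test_haufe_rejects_zero_score_variance():
    x = np.ones((10, 3))
    with pytest.raises(ValueError, match="variance"):
        haufe_transform(np.ones(3), x)


def test_group_encoding_recovers_planted_pattern_under_correlated_noise():
    """Signal and noise share a spatial band: decoder weights are pulled
    away from the generative pattern, the mean of the Haufe encodings
    recovers it."""
    data, (pv, _) = planted_group(8, 90, 150, amp=1.0, noise_sd=1.0,
                                  spatial_corr=5.0, seed=3)
    from sklearn.svm import SVC
    encs, w_rs = [], []
    for bs, lab_v, _ in data:
        encs.append(subject_encoding(bs, lab_v, n_reps=8, seed=1))
        w = SVC(kernel="linear", C=1).fit(bs.data, lab_v).coef_.ravel()
        w_rs.append(abs(np.corrcoef(w, pv)[0, 1]))
    gmap = group_maps(encs)
    enc_r = abs(np.corrcoef(gmap.mean, pv)[0, 1])
    assert enc_r > 0.8
    assert enc_r > np.mean(w_rs)


def test_group_mask_threshold_is_inclusive_at_half():
    rng = np.random.default_rng(0)
    encs = [rng.standard_normal(4) for _ in range(19)]
    masks = [np.array([True, True, True, False]) for _ in range(10)]
    masks += [np.array([True, True, False, False]) for _ in range(9)]
    # feature 2 present in 10/19 >= 50% -> included; feature 3 in 0/19
    gmap = group_maps(encs, masks=masks)
    assert gmap.mask.tolist() == [True, True, True, False]


def test_identical_encodings_flag_undefined_t():
    enc = np.arange(5.0)
    gmap = group_maps([enc.copy() for _ in range(6)])
    assert np.all(np.isnan(gmap.t))
    assert np.allclose(gmap.thresholded, 0.0)


def test_group_t_scale_matches_planted_effect_size(rng):
    # planted per-subject effect d=1 -> mean t ~ sqrt(n)
    n_sub, n_feat = 19, 300
    encs = [1.0 + rng.standard_normal(n_feat) for _ in range(n_sub)]
    gmap = group_maps(encs)
    assert np.nanmean(gmap.t) == pytest.approx(np.sqrt(n_sub), rel=0.15)


def test_cluster_filter_removes_small_islands(rng):
    n_sub = 10
    shape = (10, 10, 10)
    base = np.zeros(shape)
    base[2:6, 2:6, 2:6] = 3.0   # 64-voxel cluster: survives
    base[8, 8, 8] = 3.0         # singleton: removed
    encs = [base.ravel() + 0.1 * rng.standard_normal(1000)
            for _ in range(n_sub)]
    gmap = group_maps(encs, shape=shape, min_cluster=20)
    grid = gmap.thresholded.reshape(shape)
    assert np.all(grid[3:5, 3:5, 3:5] != 0)
    assert grid[8, 8, 8] == 0


def test_compare_encodings_exact_linear_relation(rng):
    enc_a = [rng.standard_normal(200) for _ in range(6)]
    gmap_a = group_maps(enc_a)
    gmap_b = group_maps([2.0 * e for e in enc_a])
    res = compare_encodings(gmap_a, gmap_b)
    assert res["r"] == pytest.approx(1.0)
    assert res["slope"] == pytest.approx(2.0, abs=1e-8)


def test_compare_encodings_null_maps_uncorrelated(rng):
    gmap_a = group_maps([rng.standard_normal(500) for _ in range(6)])
    gmap_b = group_maps([rng.standard_normal(500) for _ in range(6)])
    res = compare_encodings(gmap_a, gmap_b)
    assert abs(res["r"]) < 0.15
    assert res["p"] > 0.01


def test_joint_significant_mode_errors_on_noise_maps(rng):
    # pure-noise maps leave (almost) no jointly significant features
    gmap_a = group_maps([rng.standard_normal(30) for _ in range(5)])
    gmap_b = group_maps([rng.standard_normal(30) for _ in range(5)])
    with pytest.raises(ValueError, match="fewer than 3"):
        compare_encodings(gmap_a, gmap_b, mode="joint_significant")


def test_mean_of_encodings_differs_from_encoding_of_mean():
    """On heterogeneous subjects the construction order matters: averaging
    the per-subject encodings is not the encoding of the averaged decoder."""
    rng = np.random.default_rng(7)
    from sklearn.svm import SVC
    n_feat = 40
    encs, weights, all_x = [], [], []
    for s in range(6):
        scale = rng.uniform(0.5, 3.0, n_feat)  # heterogeneous covariance
        x = rng.standard_normal((80, n_feat)) * scale
        lab = np.where(rng.random(80) < 0.5, 1, -1)
        lab[:2], lab[2:4] = 1, -1
        x += np.outer(lab, rng.standard_normal(n_feat) * 0.5)
        clf = SVC(kernel="linear", C=1).fit(x, lab)
        w = clf.coef_.ravel()
        encs.append(haufe_transform(w, x))
        weights.append(w)
        all_x.append(x)
    mean_of_enc = np.mean(encs, axis=0)
    enc_of_mean = haufe_transform(np.mean(weights, axis=0), np.vstack(all_x))
    cos = (mean_of_enc @ enc_of_mean
           / np.linalg.norm(mean_of_enc) / np.linalg.norm(enc_of_mean))
    assert cos < 0.999  # demonstrably different objects
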