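"""From decoding hyperplanes to encoding maps.

A linear decoder's weight vector is not interpretable voxel-wise; the
corresponding *encoding* (activation) pattern is obtained by projecting the
weights through the feature covariance and normalising by the decision
score variance: ``A = Cov(X) w / Var(X w)``. Per-subject encodings are
averaged and t-tested feature-wise into group maps ("mean of the encodings
rather than the encoding of the mean"), and maps from different studies
are compared by robust regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import ndimage, stats
from sklearn.svm import SVC

from .lss import BetaSeries
from .mvpa import balanced_fold, _subject_key

__all__ = ["EncodingMap", "haufe_transform", "subject_encoding",
           "group_maps", "compare_encodings"]


@dataclass
class EncodingMap:
    """Group-level encoding summary over a shared feature mask."""

    mean: np.ndarray          # group mean encoding per masked feature
    t: np.ndarray             # one-sample t per feature (NaN where SD = 0)
    mask: np.ndarray          # boolean group feature mask (full feature length)
    n_subjects: int
    thresholded: np.ndarray | None = None  # mean map after |t| and cluster filters
    per_subject: np.ndarray | None = None  # subjects x masked features


def haufe_transform(weights: np.ndarray, x_train: np.ndarray) -> np.ndarray:
    """Encoding pattern of a linear decoder.

    ``A = Cov(X) w / Var(w^T X)`` with covariances estimated on the
    training data. Scaling all features by a constant rescales the
    encoding consistently; for white (identity-covariance) features the
    encoding is proportional to the weights.
    """
    x = np.asarray(x_train, float)
    w = np.asarray(weights, float)
    if w.shape[0] != x.shape[1]:
        raise ValueError("weight length must equal feature count")
    xc = x - x.mean(axis=0)
    scores = xc @ w
    var = scores.var(ddof=1)
    if var <= 0:
        raise ValueError("zero decision-score variance")
    cov_xs = xc.T @ scores / (len(scores) - 1)
    return cov_xs / var


def subject_encoding(betas: BetaSeries, labels: np.ndarray,
                     n_reps: int = 30, seed: int = 0, C: float = 1.0
                     ) -> np.ndarray:
    """Mean encoding of one subject's property decoder.

    Fits a balanced linear SVM to the full stimulus set once per
    repetition (fresh majority down-sampling each time), Haufe-transforms
    each fit on its own training data, and averages the encodings.
    """
    labels = np.asarray(labels, int)
    skey = _subject_key(betas.subject)
    enc = np.zeros(betas.n_features)
    for rep in range(n_reps):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, skey, rep, len(labels)]))
        # balanced draw over the full set: reuse the fold machinery with a
        # virtual held-out index outside the data
        idx = balanced_fold(np.append(labels, 0), len(labels), rng)
        clf = SVC(kernel="linear", C=C)
        clf.fit(betas.data[idx], labels[idx])
        enc += haufe_transform(clf.coef_.ravel(), betas.data[idx])
    return enc / n_reps


def group_maps(encodings: list[np.ndarray],
               masks: list[np.ndarray] | None = None,
               mask_threshold: float = 0.5,
               t_threshold: float = 2.10,
               min_cluster: int = 20,
               shape: tuple | None = None) -> EncodingMap:
    """Aggregate per-subject encodings into group mean and t maps.

    Features enter the group mask when present in at least
    ``mask_threshold`` of the subject masks (strictly more than half is not
    required: >= 50% includes the boundary). Features with zero
    across-subject variance get an undefined (NaN) t and are excluded from
    the thresholded map. When ``shape`` describes a voxel grid, the
    |t|-thresholded map is additionally filtered to connected clusters of
    at least ``min_cluster`` features (face adjacency); for abstract
    feature lattices the cluster filter is skipped.
    """
    if len(encodings) < 2:
        raise ValueError("group maps need at least 2 subjects")
    enc = np.vstack(encodings)
    n_sub, n_feat = enc.shape
    if masks is None:
        mask = np.ones(n_feat, bool)
    else:
        counts = np.vstack([np.asarray(m, bool) for m in masks]).sum(axis=0)
        mask = counts >= mask_threshold * len(masks)
    sub = enc[:, mask]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n_sub)), np.nan)

    thr_full = np.zeros(n_feat)
    sig = np.zeros(n_feat, bool)
    sig[np.flatnonzero(mask)] = np.isfinite(t) & (np.abs(t) > t_threshold)
    if shape is not None and len(shape) > 1:
        grid = sig.reshape(shape)
        structure = ndimage.generate_binary_structure(grid.ndim, 1)
        labels_, n_clusters = ndimage.label(grid, structure=structure)
        for c in range(1, n_clusters + 1):
            if (labels_ == c).sum() < min_cluster:
                grid[labels_ == c] = False
        sig = grid.ravel()
    mean_full = np.zeros(n_feat)
    mean_full[np.flatnonzero(mask)] = mean
    thr_full[sig] = mean_full[sig]

    return EncodingMap(mean=mean, t=t, mask=mask, n_subjects=n_sub,
                       thresholded=thr_full, per_subject=sub)


def compare_encodings(map_a: EncodingMap, map_b: EncodingMap,
                      mode: str = "all_joint_mask",
                      alpha: float = 0.05) -> dict:
    """Robust regression of one study's encoding map on another's.

    ``mode="all_joint_mask"`` compares over every feature present in both
    group masks; ``mode="joint_significant"`` keeps only features
    group-wise significant (two-sided one-sample t) in *both* maps. The fit
    is iteratively reweighted least squares with bisquare weights; ``r`` is
    the Pearson correlation of the paired values and ``p`` the slope test.
    """
    if mode not in ("all_joint_mask", "joint_significant"):
        raise ValueError("unknown comparison mode")
    joint = map_a.mask & map_b.mask
    if not np.any(joint):
        raise ValueError("empty joint feature mask")

    def _expand(m: EncodingMap, arr: np.ndarray) -> np.ndarray:
        full = np.full(m.mask.shape, np.nan)
        full[np.flatnonzero(m.mask)] = arr
        return full

    a_mean, b_mean = _expand(map_a, map_a.mean), _expand(map_b, map_b.mean)
    keep = joint.copy()
    if mode == "joint_significant":
        ta, tb = _expand(map_a, map_a.t), _expand(map_b, map_b.t)
        crit_a = stats.t.ppf(1 - alpha / 2, map_a.n_subjects - 1)
        crit_b = stats.t.ppf(1 - alpha / 2, map_b.n_subjects - 1)
        keep &= np.nan_to_num(np.abs(ta)) > crit_a
        keep &= np.nan_to_num(np.abs(tb)) > crit_b
    if keep.sum() < 3:
        raise ValueError("fewer than 3 features in the comparison subset")

    a, b = a_mean[keep], b_mean[keep]
    rlm = sm.RLM(b, sm.add_constant(a), M=sm.robust.norms.TukeyBiweight()).fit()
    r, _ = stats.pearsonr(a, b)
    return {"slope": float(rlm.params[1]),
            "intercept": float(rlm.params[0]),
            "r": float(r),
            "p": float(rlm.pvalues[1]),
            "n_features": int(keep.sum()),
            "mode": mode}
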