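"""Balanced leave-one-out SVM decoding of affect and SCR regression.

Classification is intra-subject leave-one-stimulus-out with class-balanced
training sets: within each fold the minority class is kept whole and the
majority class is randomly down-sampled to match, so chance is exactly 0.5.
The whole cross-validation is repeated (default 30 times) to average over
the down-sampling, with per-fold RNG streams derived from (seed, subject,
repetition, fold) so repetitions are independent yet reproducible.

Predictions land in a *prediction table*: one row per (subject, stimulus,
property, repetition) holding the true label, the predicted label and the
signed hyperplane distance.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC, SVR

from .lss import BetaSeries

__all__ = ["loocv_classify", "loocv_regress_scr", "accuracy_summary",
           "affective_state_accuracy", "balanced_fold", "PREDICTION_COLUMNS"]

PREDICTION_COLUMNS = ["subject", "stimulus_id", "property", "repetition",
                      "y_true", "y_pred", "decision_value"]


def _subject_key(subject) -> int:
    if isinstance(subject, (int, np.integer)):
        return int(subject)
    return zlib.crc32(str(subject).encode())


def balanced_fold(labels: np.ndarray, test_idx: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Balanced training indices for one leave-one-out fold.

    The held-out stimulus is excluded; the minority class of the remainder
    is kept whole and an equally sized random subset of the majority class
    joins it, giving |train| = 2 * N_min with equal class counts.
    """
    train = np.delete(np.arange(len(labels)), test_idx)
    pos = train[labels[train] == 1]
    neg = train[labels[train] == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("a class is (nearly) absent from training after hold-out")
    if len(pos) < len(neg):
        minority, majority = pos, neg
    else:
        minority, majority = neg, pos
    reduced = rng.choice(majority, size=len(minority), replace=False)
    fold = np.concatenate([minority, reduced])
    fold.sort()
    return fold


def loocv_classify(betas: BetaSeries, labels: np.ndarray, property_name: str,
                   n_reps: int = 30, seed: int = 0, C: float = 1.0) -> pd.DataFrame:
    """Balanced leave-one-out linear-SVM classification for one subject.

    ``labels`` must align with the beta rows and take values in {+1, -1}.
    Returns a prediction table with ``n_trials * n_reps`` rows.
    """
    labels = np.asarray(labels, int)
    if set(np.unique(labels)) - {-1, 1}:
        raise ValueError("labels must be +1/-1")
    if len(labels) != betas.n_trials:
        raise ValueError("one label per trial required")
    # canonicalise trial order by stimulus id so results (including the
    # per-fold balancing draws) are invariant to input row order
    order = np.argsort(betas.stimulus_ids, kind="stable")
    x = betas.data[order]
    labels = labels[order]
    ids = betas.stimulus_ids[order]
    n = betas.n_trials
    gram = x @ x.T
    skey = _subject_key(betas.subject)

    rows = []
    for rep in range(n_reps):
        for j in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, skey, rep, j]))
            fold = balanced_fold(labels, j, rng)
            clf = SVC(kernel="precomputed", C=C)
            clf.fit(gram[np.ix_(fold, fold)], labels[fold])
            dec = float(clf.decision_function(gram[j, fold][None, :])[0])
            rows.append((betas.subject, ids[j], property_name,
                         rep, labels[j], 1 if dec > 0 else -1, dec))
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def loocv_regress_scr(betas: BetaSeries, scr_betas: BetaSeries,
                      C: float = 1.0, epsilon: float = 0.1) -> pd.DataFrame:
    """Leave-one-out linear SVM regression of SCR amplitudes from patterns.

    No class balancing applies (the target is continuous) and the fit is
    deterministic, so there is a single repetition. Trials present in both
    series (matched by stimulus id, in the pattern series' order) are used.
    """
    scr_map = {sid: v for sid, v in
               zip(scr_betas.stimulus_ids, scr_betas.data[:, 0])}
    keep = np.array([sid in scr_map for sid in betas.stimulus_ids])
    if not np.any(keep):
        raise ValueError("no trials shared between pattern and SCR series")
    x = betas.data[keep]
    ids = betas.stimulus_ids[keep]
    y = np.array([scr_map[sid] for sid in ids])

    rows = []
    n = len(y)
    gram = x @ x.T
    for j in range(n):
        train = np.delete(np.arange(n), j)
        reg = SVR(kernel="precomputed", C=C, epsilon=epsilon)
        reg.fit(gram[np.ix_(train, train)], y[train])
        pred = float(reg.predict(gram[j, train][None, :])[0])
        rows.append((betas.subject, ids[j], "scr", 0, y[j], pred, pred))
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def accuracy_summary(preds: pd.DataFrame, subset=None) -> dict:
    """Group accuracy with a 95% t-interval over subjects.

    Per subject: the mean over repetitions of the fold-correct fraction,
    optionally restricted to the stimulus ids in ``subset`` (which may be a
    single id set or a per-subject mapping, e.g. per-subject reliable
    sets). The group summary is the mean of subject accuracies with a
    t-interval, clipped to [0, 1].
    """
    per_subject = {}
    for subject, sub in preds.groupby("subject"):
        if subset is not None:
            ids = subset.get(subject) if isinstance(subset, dict) else subset
            sub = sub[sub["stimulus_id"].isin(list(ids))]
            if sub.empty:
                raise ValueError(f"empty stimulus subset for subject {subject!r}")
        rep_acc = (sub["y_pred"] == sub["y_true"]).groupby(sub["repetition"]).mean()
        per_subject[subject] = float(rep_acc.mean())
    accs = np.array(list(per_subject.values()))
    mean = float(accs.mean())
    if len(accs) > 1 and accs.std(ddof=1) > 0:
        half = stats.t.ppf(0.975, len(accs) - 1) * accs.std(ddof=1) / np.sqrt(len(accs))
    else:
        half = 0.0
    return {"per_subject": per_subject,
            "mean": mean,
            "ci95": (max(0.0, mean - half), min(1.0, mean + half)),
            "n_subjects": len(accs)}


def affective_state_accuracy(val_preds: pd.DataFrame,
                             aro_preds: pd.DataFrame) -> pd.DataFrame:
    """Joint (affective state) correctness table.

    A trial counts as correct when both its valence and its arousal
    predictions are correct, so chance is 0.25. Returns a prediction-table
    style frame (property "AS") whose ``y_pred == y_true`` encodes joint
    correctness; feed it to :func:`accuracy_summary`.
    """
    keys = ["subject", "stimulus_id", "repetition"]
    v = val_preds[keys + ["y_true", "y_pred"]].rename(
        columns={"y_true": "vt", "y_pred": "vp"})
    a = aro_preds[keys + ["y_true", "y_pred"]].rename(
        columns={"y_true": "at", "y_pred": "ap"})
    merged = v.merge(a, on=keys, how="inner")
    if len(merged) != len(v) or len(merged) != len(a):
        raise ValueError("valence/arousal prediction keys do not match")
    correct = (merged["vt"] == merged["vp"]) & (merged["at"] == merged["ap"])
    out = merged[keys].copy()
    out["property"] = "AS"
    out["y_true"] = 1
    out["y_pred"] = np.where(correct, 1, -1)
    out["decision_value"] = np.nan
    return out[PREDICTION_COLUMNS]
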