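import numpy as np
import pandas as pd
import pytest

from affectstates.mvpa import (accuracy_summary, affective_state_accuracy,
                               balanced_fold, loocv_classify,
                               loocv_regress_scr)
from conftest import make_betas


def test_balanced_folds_have_equal_class_counts(rng):
    labels = np.concatenate([np.ones(60, int), -np.ones(30, int)])
    rng.shuffle(labels)
    for j in (0, 17, 89):
        fold = balanced_fold(labels, j, rng)
        assert j not in fold
        n_min = min((labels[np.arange(90) != j] == 1).sum(),
                    (labels[np.arange(90) != j] == -1).sum())
        assert len(fold) == 2 * n_min
        assert (labels[fold] == 1).sum() == (labels[fold] == -1).sum()


def test_separable_data_classified_perfectly(rng):
    labels = np.repeat([1, -1], 10)
    x = np.outer(labels, np.ones(30)) * 5.0 + 0.01 * rng.standard_normal((20, 30))
    preds = loocv_classify(make_betas(x), labels, "valence", n_reps=2, seed=0)
    assert (preds["y_pred"] == preds["y_true"]).all()
    assert accuracy_summary(preds)["mean"] == 1.0


def test_classification_reproducible_and_order_invariant(rng):
    x = rng.standard_normal((20, 25))
    labels = np.repeat([1, -1], 10)
    bs = make_betas(x, ids=np.arange(100, 120))
    a = loocv_classify(bs, labels, "valence", n_reps=3, seed=5)
    b = loocv_classify(bs, labels, "valence", n_reps=3, seed=5)
    pd.testing.assert_frame_equal(a, b)
    # permuting trial order leaves per-stimulus predictions unchanged
    perm = rng.permutation(20)
    bp = make_betas(x[perm], ids=np.arange(100, 120)[perm])
    c = loocv_classify(bp, labels[perm], "valence", n_reps=3, seed=5)
    key = ["stimulus_id", "repetition"]
    merged = a.merge(c, on=key, suffixes=("_a", "_c"))
    assert (merged["y_pred_a"] == merged["y_pred_c"]).all()


def test_missing_class_raises(rng):
    labels = np.ones(10, int)
    labels[0] = -1
    with pytest.raises(ValueError, match="class"):
        loocv_classify(make_betas(rng.standard_normal((10, 5))), labels,
                       "valence", n_reps=1)


def test_regression_recovers_exact_linear_targets(rng):
    x = rng.standard_normal((40, 10))
    w = rng.standard_normal(10)
    y = x @ w
    bs = make_betas(x)
    scr = make_betas(y[:, None], modality="SCR")
    preds = loocv_regress_scr(bs, scr)
    r = np.corrcoef(preds["y_pred"], preds["y_true"])[0, 1]
    assert r > 0.99


def test_regression_on_shuffled_targets_has_no_signal(rng):
    x = rng.standard_normal((90, 10))
    y = rng.permutation(x @ rng.standard_normal(10))
    preds = loocv_regress_scr(make_betas(x), make_betas(y[:, None],
                                                        modality="SCR"))
    assert abs(np.corrcoef(preds["y_pred"], preds["y_true"])[0, 1]) < 0.25


def test_constant_targets_give_constant_predictions(rng):
    x = rng.standard_normal((20, 5))
    y = np.full(20, 1.3)
    preds = loocv_regress_scr(make_betas(x), make_betas(y[:, None],
                                                        modality="SCR"))
    assert preds["y_pred"].std() < 0.2


def _pred_table(subject_accs, n_trials=10):
    rows = []
    for s, acc in enumerate(subject_accs):
        n_correct = int(round(acc * n_trials))
        for j in range(n_trials):
            correct = j < n_correct
            rows.append((s, j, "valence", 0, 1, 1 if correct else -1, 0.0))
    return pd.DataFrame(rows, columns=["subject", "stimulus_id", "property",
                                       "repetition", "y_true", "y_pred",
                                       "decision_value"])


def test_accuracy_summary_t_interval():
    summary = accuracy_summary(_pred_table([0.5, 0.6, 0.7]))
    assert summary["mean"] == pytest.approx(0.6)
    lo, hi = summary["ci95"]
    assert lo == pytest.approx(0.352, abs=0.001)
    assert hi == pytest.approx(0.848, abs=0.001)


def test_accuracy_summary_perfect_and_empty_subset():
    perfect = accuracy_summary(_pred_table([1.0, 1.0]))
    assert perfect["mean"] == 1.0 and perfect["ci95"] == (1.0, 1.0)
    with pytest.raises(ValueError, match="subset"):
        accuracy_summary(_pred_table([0.5]), subset={99})


def test_affective_state_joint_correctness():
    v = _pred_table([1.0])
    a = _pred_table([1.0])
    both = affective_state_accuracy(v, a)
    assert accuracy_summary(both)["mean"] == 1.0
    a_wrong = _pred_table([0.0])
    none = affective_state_accuracy(v, a_wrong)
    assert accuracy_summary(none)["mean"] == 0.0
    # independent fair coins -> joint accuracy ~ 0.25
    rng = np.random.default_rng(0)
    n = 4000
    rows_v, rows_a = [], []
    for j in range(n):
        rows_v.append((0, j, "valence", 0, 1,
                       1 if rng.random() < 0.5 else -1, 0.0))
        rows_a.append((0, j, "arousal", 0, 1,
                       1 if rng.random() < 0.5 else -1, 0.0))
    cols = ["subject", "stimulus_id", "property", "repetition", "y_true",
            "y_pred", "decision_value"]
    joint = affective_state_accuracy(pd.DataFrame(rows_v, columns=cols),
                                     pd.DataFrame(rows_a, columns=cols))
    assert accuracy_summary(joint)["mean"] == pytest.approx(0.25, abs=0.03)


def test_mismatched_keys_rejected():
    v = _pred_table([0.5])
    a = _pred_table([0.5]).iloc[:-2]
    with pytest.raises(ValueError, match="match"):
        affective_state_accuracy(v, a)
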