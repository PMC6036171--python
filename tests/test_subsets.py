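import numpy as np
import pandas as pd
import pytest
from scipy import stats

from affectstates.subsets import (binomial_critical, build_subsets,
                                  simulate_chance_subset_size)


def _tail_oracle(n, alpha, tail):
    """Exhaustive tail-sum search, independent of the implementation."""
    from math import comb
    pmf = [comb(n, k) * 0.5 ** n for k in range(n + 1)]
    if tail == "upper":
        for k in range(n + 1):
            if sum(pmf[k:]) < alpha:
                return k
        return n + 1
    for k in range(n, -1, -1):
        if sum(pmf[: k + 1]) < alpha:
            return k
    return -1


@pytest.mark.parametrize("n, alpha, tail, expected", [
    (18, 0.05, "upper", 13),
    (18, 0.05, "lower", 5),
    (19, 0.05, "upper", 14),
    (19, 0.05, "lower", 5),
])
def test_binomial_criticals_match_exact_tail_sums(n, alpha, tail, expected):
    assert binomial_critical(n, alpha, tail) == expected
    assert _tail_oracle(n, alpha, tail) == expected


@pytest.mark.parametrize("n", [5, 10, 18, 19, 30, 90])
def test_binomial_criticals_agree_with_oracle_across_sizes(n):
    for tail in ("upper", "lower"):
        assert binomial_critical(n, 0.05, tail) == _tail_oracle(n, 0.05, tail)


def _pred_table(correct):
    """correct: subjects x stimuli boolean matrix -> prediction table."""
    rows = []
    n_sub, n_stim = correct.shape
    for s in range(n_sub):
        for j in range(n_stim):
            rows.append((s, j, "valence", 0, 1, 1 if correct[s, j] else -1,
                         0.0))
    return pd.DataFrame(rows, columns=["subject", "stimulus_id", "property",
                                       "repetition", "y_true", "y_pred",
                                       "decision_value"])


def test_build_subsets_membership_rules():
    n_sub, n_stim = 19, 6
    correct = np.zeros((n_sub, n_stim), bool)
    correct[:, 0] = True            # all others correct -> RSS for everyone
    correct[: n_sub // 2, 1] = True  # ~half correct -> neither set
    # stimulus 2 stays all-wrong -> USS
    part = build_subsets(_pred_table(correct))
    assert part.critical_upper == 13 and part.critical_lower == 5
    for s in range(n_sub):
        assert 0 in part.rss[s]
        assert 1 not in part.rss[s] and 1 not in part.uss[s]
        assert 2 in part.uss[s]
    assert 0 in part.joint_rss and 2 in part.joint_uss


def test_build_subsets_requires_complete_predictions():
    correct = np.ones((4, 3), bool)
    table = _pred_table(correct).iloc[:-1]
    with pytest.raises(ValueError, match="every"):
        build_subsets(table)


def test_majority_vote_over_repetitions():
    rows = []
    for rep in range(3):
        for s in range(3):
            # stimulus 0: correct in 2/3 repetitions -> counts correct
            rows.append((s, 0, "valence", rep, 1, 1 if rep < 2 else -1, 0.0))
            # stimulus 1: correct in 1/3 -> counts incorrect
            rows.append((s, 1, "valence", rep, 1, 1 if rep == 0 else -1, 0.0))
    table = pd.DataFrame(rows, columns=["subject", "stimulus_id", "property",
                                        "repetition", "y_true", "y_pred",
                                        "decision_value"])
    part = build_subsets(table)
    ev = part.evidence.set_index(["subject", "stimulus_id"])
    assert ev.loc[(0, 0), "correct_among_others"] == 2
    assert ev.loc[(0, 1), "correct_among_others"] == 0


def test_chance_simulation_matches_exact_binomial_tails():
    sim = simulate_chance_subset_size(0.5, n_subjects=19, n_stimuli=90,
                                      n_sims=2000, seed=1)
    expected = stats.binom(19, 0.5).sf(13)  # P(X >= 14) = 0.0318
    assert sim["critical_upper"] == 14 and sim["critical_lower"] == 5
    assert sim["expected_rss_fraction"] == pytest.approx(expected, abs=0.004)
    assert sim["expected_uss_fraction"] == pytest.approx(expected, abs=0.004)


def test_chance_simulation_biased_coin_oracle():
    # P(Bin(19, 0.61) >= 14), exact
    expected = stats.binom(19, 0.61).sf(13)
    sim = simulate_chance_subset_size(0.61, n_sims=2000, seed=2)
    assert sim["expected_rss_fraction"] == pytest.approx(expected, abs=0.01)


def test_chance_simulation_certain_coin():
    sim = simulate_chance_subset_size(1.0, n_sims=100, seed=0,
                                      observed_rss=90)
    assert np.all(sim["rss_sizes"] == 90)
    assert sim["p_rss"] == 1.0
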