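"""Reliable and unreliable stimulus sets from group prediction evidence.

For each subject i and stimulus j, the predictions of the *other* n-1
subjects form a binomial experiment against chance 0.5. Stimuli classified
correctly by significantly many of the others (exact upper tail < alpha)
enter the subject's reliable set RSS_i; stimuli classified correctly by
significantly few enter the unreliable set USS_i. Group-level RSS/USS are
the stimuli common to every subject's set. A biased-coin simulation
provides the chance distribution of subset sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SubsetPartition", "binomial_critical", "build_subsets",
           "simulate_chance_subset_size", "correctness_matrix"]


@dataclass
class SubsetPartition:
    """Per-subject and joint reliable/unreliable stimulus sets."""

    rss: dict            # subject -> set of stimulus ids
    uss: dict
    joint_rss: set
    joint_uss: set
    evidence: pd.DataFrame   # per (subject, stimulus): correct count among others
    critical_upper: int
    critical_lower: int
    n_others: int

    def __post_init__(self) -> None:
        for s in self.rss:
            if self.rss[s] & self.uss[s]:
                raise ValueError("RSS and USS overlap")


def binomial_critical(n: int, alpha: float = 0.05, tail: str = "upper") -> int:
    """Exact binomial critical count against chance 0.5.

    upper: the smallest k with P(X >= k) < alpha; lower: the largest k with
    P(X <= k) < alpha, X ~ Bin(n, 1/2). For n = 18, alpha = 0.05 these are
    13 and 5.
    """
    if n < 1 or not 0 < alpha < 1:
        raise ValueError("need n >= 1 and 0 < alpha < 1")
    dist = stats.binom(n, 0.5)
    if tail == "upper":
        for k in range(n + 1):
            if dist.sf(k - 1) < alpha:
                return k
        return n + 1  # unattainable: no count is significant
    if tail == "lower":
        for k in range(n, -1, -1):
            if dist.cdf(k) < alpha:
                return k
        return -1
    raise ValueError("tail must be 'upper' or 'lower'")


def correctness_matrix(preds: pd.DataFrame, rep_rule: str = "majority"
                       ) -> pd.DataFrame:
    """Per (subject, stimulus) boolean correctness.

    With stochastic repetitions a subject's verdict on a stimulus is the
    strict majority vote over repetitions (ties count as incorrect); the
    ``per_repetition`` rule instead keeps the first repetition only.
    """
    correct = (preds["y_pred"] == preds["y_true"])
    if rep_rule == "majority":
        frac = correct.groupby([preds["subject"], preds["stimulus_id"]]).mean()
        return (frac > 0.5).unstack("stimulus_id")
    if rep_rule == "per_repetition":
        first = preds[preds["repetition"] == preds["repetition"].min()]
        c = (first["y_pred"] == first["y_true"])
        return c.groupby([first["subject"], first["stimulus_id"]]).any().unstack()
    raise ValueError("rep_rule must be 'majority' or 'per_repetition'")


def build_subsets(preds: pd.DataFrame, alpha: float = 0.05,
                  rep_rule: str = "majority") -> SubsetPartition:
    """Build RSS_i / USS_i and the joint group sets from a prediction table."""
    cmat = correctness_matrix(preds, rep_rule)
    if cmat.isna().any().any():
        raise ValueError("every stimulus must be predicted for every subject")
    subjects = list(cmat.index)
    n_others = len(subjects) - 1
    if n_others < 1:
        raise ValueError("subset selection needs at least 2 subjects")
    k_up = binomial_critical(n_others, alpha, "upper")
    k_lo = binomial_critical(n_others, alpha, "lower")

    counts = cmat.to_numpy(bool).astype(int)
    totals = counts.sum(axis=0)
    rss, uss, rows = {}, {}, []
    for i, subject in enumerate(subjects):
        others = totals - counts[i]
        rss[subject] = set(cmat.columns[others >= k_up])
        uss[subject] = set(cmat.columns[others <= k_lo])
        for j, sid in enumerate(cmat.columns):
            rows.append((subject, sid, int(others[j])))
    evidence = pd.DataFrame(rows, columns=["subject", "stimulus_id",
                                           "correct_among_others"])
    joint_rss = set.intersection(*rss.values()) if rss else set()
    joint_uss = set.intersection(*uss.values()) if uss else set()
    return SubsetPartition(rss=rss, uss=uss, joint_rss=joint_rss,
                           joint_uss=joint_uss, evidence=evidence,
                           critical_upper=k_up, critical_lower=k_lo,
                           n_others=n_others)


def simulate_chance_subset_size(mean_acc: float, n_subjects: int = 19,
                                n_stimuli: int = 90, n_sims: int = 1000,
                                alpha: float = 0.05,
                                seed: int | np.random.Generator = 0,
                                observed_rss: int | None = None,
                                observed_uss: int | None = None) -> dict:
    """Chance distribution of apparent subset sizes under a biased coin.

    Each simulated stimulus receives ``n_subjects`` coin flips with
    P(correct) = ``mean_acc``; a stimulus is flagged reliable (unreliable)
    when its head count reaches the exact Bin(n_subjects, 1/2) upper
    (lower) critical. Reported p-values are the fraction of simulations
    with a flagged set at least as large as observed.
    """
    if not 0.0 <= mean_acc <= 1.0:
        raise ValueError("mean_acc must be a probability")
    rng = np.random.default_rng(seed)
    k_up = binomial_critical(n_subjects, alpha, "upper")
    k_lo = binomial_critical(n_subjects, alpha, "lower")
    heads = rng.binomial(n_subjects, mean_acc, size=(n_sims, n_stimuli))
    rss_sizes = (heads >= k_up).sum(axis=1)
    uss_sizes = (heads <= k_lo).sum(axis=1)
    out = {"rss_sizes": rss_sizes, "uss_sizes": uss_sizes,
           "critical_upper": k_up, "critical_lower": k_lo,
           "expected_rss_fraction": float((heads >= k_up).mean()),
           "expected_uss_fraction": float((heads <= k_lo).mean())}
    if observed_rss is not None:
        out["p_rss"] = float((rss_sizes >= observed_rss).mean())
    if observed_uss is not None:
        out["p_uss"] = float((uss_sizes >= observed_uss).mean())
    return out
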