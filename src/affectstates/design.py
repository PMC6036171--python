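"""Constrained experimental designs for the affect induction task.

A design presents stimuli in two formats: *extrinsic* (2-s passive
viewing) and *intrinsic* (2-s viewing, 2-s cue, 10-s volitional
re-experiencing). Presentations are separated by inter-trial intervals
drawn uniformly from 2-6 s. Candidate orders and ITIs are rejection-sampled
until four criteria hold simultaneously:

1. each run begins with an extrinsic trial,
2. no more than three consecutive intrinsic trials,
3. each run begins and ends with a positive-valence stimulus,
4. all pairwise Pearson correlations among the four HRF-convolved affect
   category regressors (positive/negative valence, high/low arousal) stay
   below a threshold (default 0.25).

Accepted designs carry a constraint report and are re-verifiable with the
independent :func:`check_design`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import validate_catalog
from .kernels import Kernel, hrf_kernel

__all__ = ["TrialDesign", "DesignError", "build_design", "check_design",
           "category_regressors", "max_category_correlation"]

EXTRINSIC = "extrinsic"
INTRINSIC = "intrinsic"
STIM_DURATION = 2.0          # image presentation, seconds
INTRINSIC_EXTRA = 12.0       # cue (2 s) + volitional re-experiencing (10 s)
ITI_RANGE = (2.0, 6.0)


class DesignError(RuntimeError):
    """Raised when no admissible design is found within the attempt budget."""


@dataclass
class TrialDesign:
    """The experimental timeline.

    Attributes
    ----------
    events
        One row per trial: ``onset`` (s, within run), ``duration`` (s),
        ``trial_type`` ("extrinsic"/"intrinsic"), ``stimulus_id``, ``run``
        (0-based), ``iti`` (s).
    tr
        Repetition time of volume acquisition, seconds.
    run_length_s
        Length of each run, seconds (all runs equal).
    censor
        Optional boolean keep-mask over concatenated volumes (True = keep).
    report
        Constraint report attached by :func:`build_design`.
    """

    events: pd.DataFrame
    tr: float = 2.0
    run_length_s: float = 0.0
    censor: np.ndarray | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"onset", "duration", "trial_type", "stimulus_id", "run", "iti"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"events missing columns: {sorted(missing)}")
        for _, run_ev in self.events.groupby("run"):
            onsets = run_ev["onset"].to_numpy(float)
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("onsets must be strictly increasing within a run")
            if len(onsets) and onsets[-1] >= self.run_length_s:
                raise ValueError("onset outside run bounds")

    @property
    def n_runs(self) -> int:
        return int(self.events["run"].max()) + 1

    @property
    def n_volumes_per_run(self) -> int:
        return int(np.ceil(self.run_length_s / self.tr))

    @property
    def n_volumes(self) -> int:
        return self.n_volumes_per_run * self.n_runs

    def extrinsic_events(self) -> pd.DataFrame:
        return self.events[self.events["trial_type"] == EXTRINSIC].reset_index(drop=True)

    def iti_summary(self) -> tuple[float, float]:
        itis = self.events["iti"].to_numpy(float)
        return float(itis.mean()), float(itis.std(ddof=1))


def _trial_duration(trial_type: str) -> float:
    return STIM_DURATION + (INTRINSIC_EXTRA if trial_type == INTRINSIC else 0.0)


def _assemble(order: pd.DataFrame, itis: np.ndarray, lead_in: float) -> np.ndarray:
    """Cumulative onsets for one run given trial order and per-trial ITIs."""
    onsets = np.empty(len(order))
    t = lead_in
    for k, (_, row) in enumerate(order.iterrows()):
        onsets[k] = t
        t += _trial_duration(row["trial_type"]) + itis[k]
    return onsets


def category_regressors(design: TrialDesign, catalog: pd.DataFrame,
                        hrf: Kernel | None = None,
                        mode: str = "discrete") -> np.ndarray:
    """HRF-convolved affect category regressors over concatenated runs.

    ``mode="discrete"`` (default) partitions stimuli into the four
    mutually exclusive affect quadrants of the arousal-valence plane
    (labels vs the Likert midpoint): positive-valence/high-arousal,
    positive/low, negative/high, negative/low. A partition is the only
    construction under which "all pairwise correlations below threshold"
    is attainable: categories sharing stimuli (a stimulus is always both a
    valence and an arousal exemplar) put a floor of roughly
    ``n_shared / sqrt(n_i * n_j)`` under the between-category correlation,
    irrespective of trial timing.

    ``mode="overlapping"`` returns the four marginal label regressors
    (positive valence, negative valence, high arousal, low arousal) for
    diagnostics; ``mode="per_trial"`` returns one regressor per trial.

    Events are the 2-s image presentations of *all* trial formats, sampled
    at the TR grid.
    """
    validate_catalog(catalog, require_labels=True)
    if hrf is None:
        hrf = hrf_kernel(dt=0.1, stim_duration=STIM_DURATION)
    lab = catalog.set_index("stimulus_id")
    dt = hrf.dt
    nvol = design.n_volumes_per_run
    vol_idx = np.rint(np.arange(nvol) * design.tr / dt).astype(int)
    n_fine = max(int(round(design.run_length_s / dt)), int(vol_idx[-1]) + 1)

    if mode == "discrete":
        groups = [lambda s: lab.loc[s, "val_label"] == 1 and lab.loc[s, "aro_label"] == 1,
                  lambda s: lab.loc[s, "val_label"] == 1 and lab.loc[s, "aro_label"] == -1,
                  lambda s: lab.loc[s, "val_label"] == -1 and lab.loc[s, "aro_label"] == 1,
                  lambda s: lab.loc[s, "val_label"] == -1 and lab.loc[s, "aro_label"] == -1]
    elif mode == "overlapping":
        groups = [lambda s: lab.loc[s, "val_label"] == 1,
                  lambda s: lab.loc[s, "val_label"] == -1,
                  lambda s: lab.loc[s, "aro_label"] == 1,
                  lambda s: lab.loc[s, "aro_label"] == -1]
    elif mode == "per_trial":
        groups = None
    else:
        raise ValueError("mode must be 'discrete', 'overlapping' or 'per_trial'")

    def _convolve_events(member) -> np.ndarray:
        runs = []
        for r in range(design.n_runs):
            ev = design.events[design.events["run"] == r]
            impulses = np.zeros(n_fine)
            for _, row in ev.iterrows():
                if member(row):
                    impulses[int(round(row["onset"] / dt))] = 1.0
            runs.append(hrf.convolve(impulses)[vol_idx])
        return np.concatenate(runs)

    if groups is None:
        cols = [_convolve_events(lambda row, k=k: row.name == k)
                for k in design.events.index]
    else:
        cols = [_convolve_events(lambda row, g=g: g(row["stimulus_id"]))
                for g in groups]
    return np.column_stack(cols)


def max_category_correlation(design: TrialDesign, catalog: pd.DataFrame,
                             hrf: Kernel | None = None,
                             mode: str = "discrete") -> float:
    """Largest absolute pairwise Pearson correlation among category regressors.

    Zero-variance (empty-category) regressors are excluded from the pairs.
    """
    reg = category_regressors(design, catalog, hrf, mode)
    keep = reg.std(axis=0) > 0
    reg = reg[:, keep]
    if reg.shape[1] < 2:
        return 0.0
    corr = np.corrcoef(reg.T)
    return float(np.max(np.abs(corr[np.triu_indices(reg.shape[1], k=1)])))


def _check_order(run_types: list[str], run_pos_val: list[bool]) -> str | None:
    """Return the name of the first violated order criterion, or None."""
    if run_types[0] != EXTRINSIC:
        return "begins_with_extrinsic"
    consec = 0
    for t in run_types:
        consec = consec + 1 if t == INTRINSIC else 0
        if consec > 3:
            return "max_three_consecutive_intrinsic"
    if not (run_pos_val[0] and run_pos_val[-1]):
        return "begins_and_ends_positive_valence"
    return None


def build_design(catalog: pd.DataFrame,
                 extrinsic_ids: list,
                 intrinsic_ids: list | None = None,
                 n_runs: int = 2,
                 tr: float = 2.0,
                 max_corr: float = 0.25,
                 max_attempts: int = 10_000,
                 lead_in: float = 4.0,
                 tail: float = 16.0,
                 hrf: Kernel | None = None,
                 seed: int | np.random.Generator = 0) -> TrialDesign:
    """Rejection-sample an admissible design.

    Stimuli are split evenly across ``n_runs`` runs; within each run the
    trial order and the U(2, 6) ITIs are resampled until all four design
    criteria hold. On budget exhaustion a :class:`DesignError` names the
    first unmet criterion of the last attempt.
    """
    validate_catalog(catalog, require_labels=True)
    intrinsic_ids = list(intrinsic_ids or [])
    rng = np.random.default_rng(seed)
    if hrf is None:
        hrf = hrf_kernel(dt=0.1, stim_duration=STIM_DURATION)
    lab = catalog.set_index("stimulus_id")
    pos_val = {sid: lab.loc[sid, "val_label"] == 1
               for sid in list(extrinsic_ids) + intrinsic_ids}
    if not any(pos_val[s] for s in extrinsic_ids):
        raise DesignError("no positive-valence extrinsic stimuli: "
                          "criterion begins_and_ends_positive_valence unsatisfiable")

    trials = ([(s, EXTRINSIC) for s in extrinsic_ids]
              + [(s, INTRINSIC) for s in intrinsic_ids])
    per_run = len(trials) // n_runs
    counts = [per_run + (1 if r < len(trials) % n_runs else 0) for r in range(n_runs)]

    last_violation = "order_criteria"
    for attempt in range(1, max_attempts + 1):
        perm = rng.permutation(len(trials))
        shuffled = [trials[i] for i in perm]
        run_slices, start = [], 0
        for c in counts:
            run_slices.append(shuffled[start:start + c])
            start += c

        violation = None
        for run_trials in run_slices:
            types = [t for _, t in run_trials]
            posv = [pos_val[s] for s, _ in run_trials]
            violation = _check_order(types, posv)
            if violation:
                break
        if violation:
            last_violation = violation
            continue

        rows, run_len = [], 0.0
        for r, run_trials in enumerate(run_slices):
            itis = rng.uniform(*ITI_RANGE, size=len(run_trials))
            df = pd.DataFrame({"stimulus_id": [s for s, _ in run_trials],
                               "trial_type": [t for _, t in run_trials]})
            onsets = _assemble(df, itis, lead_in)
            df["onset"] = onsets
            df["duration"] = STIM_DURATION
            df["run"] = r
            df["iti"] = itis
            rows.append(df)
            end = onsets[-1] + _trial_duration(df["trial_type"].iloc[-1]) + tail
            run_len = max(run_len, end)
        run_len = float(np.ceil(run_len / tr) * tr)
        events = pd.concat(rows, ignore_index=True)
        design = TrialDesign(events=events, tr=tr, run_length_s=run_len)

        corr = max_category_correlation(design, catalog, hrf)
        if corr >= max_corr:
            last_violation = "category_regressor_correlation"
            continue

        design.report = {"attempts": attempt,
                         "max_category_correlation": corr,
                         "criteria": check_design(design, catalog, max_corr, hrf)}
        return design

    raise DesignError(
        f"no admissible design in {max_attempts} attempts; "
        f"first unmet criterion of last attempt: {last_violation}")


def check_design(design: TrialDesign, catalog: pd.DataFrame,
                 max_corr: float = 0.25, hrf: Kernel | None = None) -> dict:
    """Independently re-verify the four design criteria.

    Returns a dict mapping criterion name to bool. Deliberately separate
    from the sampler in :func:`build_design` so accepted designs are not
    self-certified.
    """
    validate_catalog(catalog, require_labels=True)
    lab = catalog.set_index("stimulus_id")
    results = {"begins_with_extrinsic": True,
               "max_three_consecutive_intrinsic": True,
               "begins_and_ends_positive_valence": True}
    for _, ev in design.events.groupby("run"):
        types = ev["trial_type"].tolist()
        posv = [lab.loc[s, "val_label"] == 1 for s in ev["stimulus_id"]]
        v = _check_order(types, posv)
        if v:
            results[v] = False
    corr = max_category_correlation(design, catalog, hrf)
    results["category_regressor_correlation"] = bool(corr < max_corr)
    results["max_category_correlation"] = corr
    return results
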