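"""Trial-wise BOLD response estimation (least-squares-separate beta-series).

One linear model is solved per trial: the trial's own HRF-convolved
regressor, one aggregate regressor per presentation format collecting all
*other* trials, per-run orthogonal-polynomial drift (order
``1 + floor(run_seconds / 150)``), optional nuisance columns, with
censored volumes excluded. The trial's coefficient is its beta. The
returned series is sub-selected to extrinsic trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import EXTRINSIC, TrialDesign
from .kernels import Kernel, hrf_kernel

__all__ = ["BetaSeries", "fit_bold_lss", "trial_regressors", "drift_basis"]

MODALITIES = ("GM", "GS", "SCR")


@dataclass
class BetaSeries:
    """Trial-by-feature response amplitudes.

    ``data`` rows follow extrinsic trial (timeline) order. ``modality``
    tags the feature space: "GM" (voxels), "GS" (Gram-Schmidt coordinates)
    or "SCR" (a single electrodermal feature).
    """

    data: np.ndarray
    modality: str
    stimulus_ids: np.ndarray
    subject: int | str = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("beta series contains non-finite entries")
        if len(self.stimulus_ids) != self.data.shape[0]:
            raise ValueError("one stimulus id per trial row required")
        if self.modality == "SCR" and self.data.shape[1] != 1:
            raise ValueError("SCR beta series must have a single feature")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def drift_basis(n_volumes: int, run_seconds: float,
                degree: int | None = None) -> np.ndarray:
    """Per-run Legendre drift columns.

    The default degree follows the run-length convention
    ``1 + floor(run_seconds / 150)``.
    """
    if degree is None:
        degree = 1 + int(run_seconds // 150)
    t = np.linspace(-1.0, 1.0, n_volumes)
    return np.column_stack([np.polynomial.legendre.Legendre.basis(d)(t)
                            for d in range(degree + 1)])


def trial_regressors(design: TrialDesign, hrf: Kernel | None = None) -> np.ndarray:
    """HRF-convolved per-trial regressors over concatenated runs.

    Returns (n_volumes_total, n_trials); each column is zero outside its
    trial's run.
    """
    if hrf is None:
        hrf = hrf_kernel(dt=0.1, stim_duration=0.0)
    dt = hrf.dt
    nvol = design.n_volumes_per_run
    vol_idx = np.rint(np.arange(nvol) * design.tr / dt).astype(int)
    n_fine = max(int(round(design.run_length_s / dt)), int(vol_idx[-1]) + 1)
    n_trials = len(design.events)
    out = np.zeros((nvol * design.n_runs, n_trials))
    for k, (_, row) in enumerate(design.events.iterrows()):
        if row["onset"] + row["duration"] > design.run_length_s:
            raise ValueError("trial extends outside run bounds")
        box = np.zeros(n_fine)
        box[int(round(row["onset"] / dt)):int(round((row["onset"] + row["duration"]) / dt))] = 1.0
        r = int(row["run"])
        out[r * nvol:(r + 1) * nvol, k] = hrf.convolve(box)[vol_idx]
    return out


def fit_bold_lss(bold_runs: list[np.ndarray], design: TrialDesign,
                 hrf: Kernel | None = None,
                 nuisance: np.ndarray | None = None,
                 censor: np.ndarray | None = None,
                 polort: int | str | None = "auto",
                 subject: int | str = 0) -> BetaSeries:
    """Least-squares-separate beta-series from concatenated BOLD runs.

    Parameters
    ----------
    bold_runs
        One (n_volumes_per_run, n_voxels) matrix per run.
    nuisance
        Optional (n_volumes_total, k) nuisance columns (e.g. motion model).
    censor
        Optional boolean keep-mask over concatenated volumes; defaults to
        ``design.censor``.
    polort
        Per-run polynomial drift degree: ``"auto"`` for the run-length rule
        in :func:`drift_basis`, an int for a fixed degree, ``None`` to omit
        drift columns entirely.
    """
    y = np.vstack([np.atleast_2d(r) for r in bold_runs])
    nvol = design.n_volumes_per_run
    if y.shape[0] != nvol * design.n_runs:
        raise ValueError("BOLD volume count does not match the design")
    regs = trial_regressors(design, hrf)

    blocks = []
    if polort is not None:
        degree = None if polort == "auto" else int(polort)
        for r in range(design.n_runs):
            b = drift_basis(nvol, design.run_length_s, degree)
            block = np.zeros((y.shape[0], b.shape[1]))
            block[r * nvol:(r + 1) * nvol] = b
            blocks.append(block)
    drift = np.hstack(blocks) if blocks else np.zeros((y.shape[0], 0))
    base = drift if nuisance is None else np.hstack([drift, np.atleast_2d(nuisance)])

    keep = np.ones(y.shape[0], bool)
    if censor is None:
        censor = design.censor
    if censor is not None:
        keep = np.asarray(censor, bool)
        if keep.shape[0] != y.shape[0]:
            raise ValueError("censor mask length does not match volume count")

    is_ext = (design.events["trial_type"] == EXTRINSIC).to_numpy()
    fmt_sums = {fmt: regs[:, design.events["trial_type"].to_numpy() == fmt].sum(axis=1)
                for fmt in design.events["trial_type"].unique()}

    n_trials = len(design.events)
    betas = np.empty((n_trials, y.shape[1]))
    yk = y[keep]
    for t in range(n_trials):
        fmt = design.events["trial_type"].iloc[t]
        cols = [regs[:, t]]
        for f, s in fmt_sums.items():
            other = s - regs[:, t] if f == fmt else s
            if np.any(other):
                cols.append(other)
        X = np.column_stack(cols + [base])[keep]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient LSS design for trial {t} after censoring")
        coef, *_ = np.linalg.lstsq(X, yk, rcond=None)
        betas[t] = coef[0]

    ext_ids = design.events.loc[is_ext, "stimulus_id"].to_numpy()
    return BetaSeries(data=betas[is_ext], modality="GM",
                      stimulus_ids=ext_ids, subject=subject)
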