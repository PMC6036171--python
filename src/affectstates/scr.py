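"""Skin-conductance preprocessing and trial-wise amplitude estimation.

The preprocessing chain (applied in this order):

1. 10-ms median filter,
2. zeroing against the mean of the first 10 ms,
3. first-order bi-directional Butterworth band-pass, 0.033-5 Hz,
4. downsampling to 10 Hz,
5. z-scoring within run.

Trial amplitudes are then estimated by ordinary least squares against
per-trial regressors built from the canonical response, passed through the
*identical* filter chain (to account for peak shifting) and z-scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import ceil

import numpy as np
from scipy import signal as sps

from .design import EXTRINSIC, TrialDesign
from .kernels import Kernel, scr_canonical
from .lss import BetaSeries

__all__ = ["preprocess_scr", "fit_scr_betas", "ProcessedSCR"]

OUT_FS = 10.0
BAND = (0.033, 5.0)
DEGENERATE_TOL = 1e-12


@dataclass
class ProcessedSCR:
    """A preprocessed trace at 10 Hz with its degeneracy flag."""

    trace: np.ndarray
    fs: float = OUT_FS
    degenerate: bool = False


def _median_filter_10ms(x: np.ndarray, fs: float) -> np.ndarray:
    half = int(round(fs * 0.01))
    if half < 1:
        return x.copy()
    return sps.medfilt(x, kernel_size=2 * half + 1)


def _filter_chain(x: np.ndarray, fs: float) -> np.ndarray:
    """Steps 1-4 of the chain (everything except per-run z-scoring)."""
    x = _median_filter_10ms(np.asarray(x, float), fs)
    n0 = max(ceil(fs * 0.01), 1)
    x = x - x[:n0].mean()
    sos = sps.butter(1, BAND, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    frac = Fraction(OUT_FS / fs).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def preprocess_scr(trace: np.ndarray, fs: float) -> ProcessedSCR:
    """Run the 5-step chain on one raw run; output at 10 Hz, mean 0, SD 1.

    A trace that is (near-)constant after band-passing cannot be z-scored;
    it is returned as zeros with ``degenerate=True`` so callers can exclude
    the run.
    """
    if fs < 20:
        raise ValueError("sampling rate must be >= 20 Hz")
    trace = np.asarray(trace, float)
    if trace.size < 4 * fs / BAND[0] / 100:
        raise ValueError("trace shorter than the filter warm-up")
    x = _filter_chain(trace, fs)
    sd = x.std()
    if sd < DEGENERATE_TOL:
        return ProcessedSCR(trace=np.zeros_like(x), degenerate=True)
    return ProcessedSCR(trace=(x - x.mean()) / sd)


def fit_scr_betas(processed: list[ProcessedSCR], design: TrialDesign,
                  fs_design: float = 100.0,
                  kernel: Kernel | None = None,
                  subject: int | str = 0,
                  condition_warn: float = 1e6) -> BetaSeries:
    """Trial-wise SCR amplitudes by canonical-response regression.

    Parameters
    ----------
    processed
        One :class:`ProcessedSCR` per run (degenerate runs are skipped and
        their trials absent from the output).
    fs_design
        Rate at which the design function is built before it is passed
        through the same filter chain as the data.
    """
    if kernel is None:
        kernel = scr_canonical(dt=1.0 / fs_design)
    if len(processed) != design.n_runs:
        raise ValueError("one processed trace per run required")

    betas, kept_ids = [], []
    for r, proc in enumerate(processed):
        if proc.degenerate:
            continue
        ev = design.events[design.events["run"] == r]
        if np.any(ev["onset"].to_numpy() > design.run_length_s):
            raise ValueError("onset outside trace span")
        n_fine = int(round(design.run_length_s * fs_design))
        cols = []
        for _, row in ev.iterrows():
            impulse = np.zeros(n_fine)
            impulse[int(round(row["onset"] * fs_design))] = 1.0
            reg = _filter_chain(kernel.convolve(impulse), fs_design)
            reg = reg[: len(proc.trace)]
            sd = reg.std()
            if sd < DEGENERATE_TOL:
                raise ValueError("degenerate SCR design regressor")
            cols.append((reg - reg.mean()) / sd)
        X = np.column_stack(cols + [np.ones(len(cols[0]))])
        cond = np.linalg.cond(X)
        if cond > condition_warn:
            warnings.warn(f"ill-conditioned SCR design (cond={cond:.3g}); "
                          "onsets may be too dense for the canonical width",
                          RuntimeWarning, stacklevel=2)
        coef, *_ = np.linalg.lstsq(X, proc.trace[: X.shape[0]], rcond=None)
        is_ext = (ev["trial_type"] == EXTRINSIC).to_numpy()
        betas.append(coef[:-1][is_ext])
        kept_ids.append(ev.loc[is_ext, "stimulus_id"].to_numpy())

    if not betas:
        raise ValueError("all runs degenerate; no SCR betas")
    return BetaSeries(data=np.concatenate(betas)[:, None], modality="SCR",
                      stimulus_ids=np.concatenate(kept_ids), subject=subject)
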