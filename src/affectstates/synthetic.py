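"""Synthetic inputs with planted ground truth.

The generator emulates the data a picture-induced affect experiment would
yield, under the working hypothesis that a trial's distributed activation
pattern linearly encodes the signed valence and arousal of the stimulus,
and that the skin-conductance response amplitude tracks arousal:

* a stimulus pool whose normative (valence, arousal) scores show the
  characteristic "boomerang" coupling of normed affective picture sets
  (arousal rises with valence extremity),
* per-subject trial-by-voxel activation patterns
  ``beta = P_v * s_v + P_a * s_a + noise`` with optional spatially
  correlated noise and an optional set of *incongruent* stimuli whose
  induced pattern contradicts the normative label,
* BOLD runs formed by HRF convolution of those trial amplitudes,
* raw skin-conductance traces formed by canonical-response convolution of
  arousal-linked event amplitudes plus slow drift and measurement noise.

All randomness flows through a single seed; regenerating with the same
configuration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .catalog import binarize_labels
from .design import EXTRINSIC, TrialDesign
from .kernels import Kernel, hrf_kernel, scr_canonical

__all__ = ["SyntheticConfig", "GroundTruth", "gen_stimulus_pool",
           "gen_encoding_patterns", "gen_subject_betas", "gen_bold", "gen_scr",
           "amplitude_for_dprime"]


@dataclass
class SyntheticConfig:
    """Generative settings for one synthetic study.

    Desk-scale defaults mirror the emulated study design: 19 subjects,
    90 extrinsic + 30 intrinsic stimuli over 2 runs, at a feasible feature
    count of 2000 voxels.
    """

    n_subjects: int = 19
    n_stimuli_pool: int = 1000
    n_extrinsic: int = 90
    n_intrinsic: int = 30
    n_voxels: int = 2000
    n_runs: int = 2
    coupling: float = 0.5           # valence-extremity -> arousal coupling
    noise_sd: float = 1.0           # activation noise, per voxel
    spatial_corr: float = 0.0       # Gaussian correlation length (voxels); 0 = white
    incongruent_fraction: float = 0.0
    amplitude_mode: str = "continuous"   # or "signed": s = label * amplitude
    signal_gain: float = 0.25       # continuous mode: s = gain * (score - 5)
    signed_amplitude: float = 1.0   # signed mode: |s| per trial
    scr_amp_slope: float = 0.3      # SCR amplitude per unit centered arousal
    scr_amp_noise_sd: float = 0.1
    scr_noise_sd: float = 0.02      # measurement noise on the trace
    drift_sd: float = 0.1           # slow drift scale on the trace
    sampling_rate: float = 100.0    # Hz (acquisition would be faster; any >= 20 works)
    tr: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.incongruent_fraction <= 1.0:
            raise ValueError("incongruent_fraction must be in [0, 1]")
        if self.sampling_rate <= 0 or self.tr <= 0:
            raise ValueError("rates must be positive")
        if self.amplitude_mode not in ("continuous", "signed"):
            raise ValueError("amplitude_mode must be 'continuous' or 'signed'")
        if self.n_voxels < self.n_extrinsic:
            raise ValueError("n_voxels must be >= number of extrinsic stimuli "
                             "(Gram-Schmidt reduction is otherwise ill-posed)")


@dataclass
class GroundTruth:
    """Planted quantities behind one subject's synthetic data."""

    pattern_valence: np.ndarray      # P_v, unit norm, length n_voxels
    pattern_arousal: np.ndarray      # P_a, unit norm, orthogonal to P_v
    amp_valence: np.ndarray          # s_v per trial (all formats, timeline order)
    amp_arousal: np.ndarray          # s_a per trial
    clean_patterns: np.ndarray       # trials x voxels, noise-free
    incongruent_ids: frozenset = frozenset()
    scr_amplitudes: np.ndarray | None = None  # planted SCR event amplitudes

    def extrinsic_rows(self, design: TrialDesign) -> np.ndarray:
        return (design.events["trial_type"] == EXTRINSIC).to_numpy()


def amplitude_for_dprime(dprime: float, noise_sd: float) -> float:
    """Signed-mode amplitude planting a given discriminability.

    With unit-norm patterns, white noise and signed amplitudes ``+-a``,
    the two classes project onto the pattern as N(+-a, noise_sd^2), so
    d' = 2a / noise_sd and an oracle discriminant scores Phi(d'/2).
    """
    return dprime * noise_sd / 2.0


def gen_stimulus_pool(n_pool: int, coupling: float = 0.5,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw a stimulus pool with boomerang-coupled normative scores.

    Valence means are uniform on [1, 9] (resampled away from exactly 5 so
    binary labels are never ambiguous); arousal means rise with valence
    extremity at strength ``coupling`` plus unit-SD scatter, clipped to
    the Likert range. Rating SDs are uniform on [0.5, 2.5].
    """
    rng = np.random.default_rng(seed)
    if n_pool == 0:
        return pd.DataFrame(columns=["stimulus_id", "val_mean", "val_sd",
                                     "aro_mean", "aro_sd"])
    val = rng.uniform(1.0, 9.0, size=n_pool)
    # keep labels unambiguous: nudge means off the exact midpoint
    near = np.abs(val - 5.0) < 1e-6
    val[near] = 5.0 + np.sign(rng.standard_normal(near.sum())) * 1e-3
    aro = 3.1 + 1.3 * coupling * np.abs(val - 5.0) + 1.1 * rng.standard_normal(n_pool)
    aro = np.clip(aro, 1.0, 9.0)
    near = np.abs(aro - 5.0) < 1e-6
    aro[near] = 5.0 + np.sign(rng.standard_normal(near.sum())) * 1e-3
    pool = pd.DataFrame({
        "stimulus_id": np.arange(1, n_pool + 1),
        "val_mean": val,
        "val_sd": rng.uniform(0.5, 2.5, size=n_pool),
        "aro_mean": aro,
        "aro_sd": rng.uniform(0.5, 2.5, size=n_pool),
    })
    return binarize_labels(pool)


def gen_encoding_patterns(n_voxels: int,
                          seed: int | np.random.Generator = 0,
                          spatial_corr: float = 0.0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Draw orthonormal valence/arousal encoding patterns.

    With ``spatial_corr > 0`` the patterns are spatially smooth at that
    correlation length (smoothed white noise on the feature lattice).
    Matching the noise correlation length puts signal and noise in the
    same spatial band — the regime where a decoder's weights are pulled
    away from the generative pattern and the decoding-to-encoding
    transform is needed to recover it.
    """
    rng = np.random.default_rng(seed)
    p_v = rng.standard_normal(n_voxels)
    p_a = rng.standard_normal(n_voxels)
    if spatial_corr > 0:
        p_v = gaussian_filter1d(p_v, sigma=spatial_corr, mode="wrap")
        p_a = gaussian_filter1d(p_a, sigma=spatial_corr, mode="wrap")
    p_v /= np.linalg.norm(p_v)
    p_a -= p_v * (p_v @ p_a)
    p_a /= np.linalg.norm(p_a)
    return p_v, p_a


def _trial_amplitudes(catalog_row, config: SyntheticConfig) -> tuple[float, float]:
    if config.amplitude_mode == "signed":
        return (config.signed_amplitude * float(catalog_row.val_label),
                config.signed_amplitude * float(catalog_row.aro_label))
    return (config.signal_gain * (float(catalog_row.val_mean) - 5.0),
            config.signal_gain * (float(catalog_row.aro_mean) - 5.0))


def _spatial_noise(rng: np.random.Generator, shape: tuple[int, int],
                   sd: float, corr_len: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if corr_len > 0:
        # smooth white noise on the 1-D feature lattice, rescaled so the
        # marginal SD stays `sd`
        noise = gaussian_filter1d(noise, sigma=corr_len, axis=1, mode="wrap")
        noise /= np.sqrt(1.0 / (2.0 * np.sqrt(np.pi) * corr_len))
        noise /= noise.std()
    return sd * noise


def pick_incongruent(stimulus_ids: np.ndarray, fraction: float,
                     rng: np.random.Generator) -> frozenset:
    n_flip = int(round(fraction * len(stimulus_ids)))
    if n_flip == 0:
        return frozenset()
    return frozenset(rng.choice(stimulus_ids, size=n_flip, replace=False).tolist())


def gen_subject_betas(catalog: pd.DataFrame, design: TrialDesign,
                      config: SyntheticConfig,
                      patterns: tuple[np.ndarray, np.ndarray] | None = None,
                      incongruent_ids: frozenset | None = None,
                      seed: int | np.random.Generator = 0
                      ) -> tuple[np.ndarray, GroundTruth]:
    """One subject's trial-by-voxel activation patterns plus ground truth.

    Returns the noisy pattern matrix over *all* trials in timeline order
    (extrinsic sub-selection is the downstream stage's job) and the
    :class:`GroundTruth` that generated it. ``patterns`` and
    ``incongruent_ids`` are shared across subjects of one study; per-subject
    noise comes from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_trials = len(design.events)
    if config.n_voxels < (design.events["trial_type"] == EXTRINSIC).sum():
        raise ValueError("n_voxels smaller than the number of extrinsic trials")
    if patterns is None:
        patterns = gen_encoding_patterns(config.n_voxels, rng)
    p_v, p_a = patterns
    if incongruent_ids is None:
        ext_ids = design.extrinsic_events()["stimulus_id"].to_numpy()
        incongruent_ids = pick_incongruent(ext_ids, config.incongruent_fraction, rng)

    lab = catalog.set_index("stimulus_id")
    s_v = np.empty(n_trials)
    s_a = np.empty(n_trials)
    for k, sid in enumerate(design.events["stimulus_id"]):
        a_v, a_a = _trial_amplitudes(lab.loc[sid], config)
        if sid in incongruent_ids:
            a_v, a_a = -a_v, -a_a
        s_v[k], s_a[k] = a_v, a_a

    clean = np.outer(s_v, p_v) + np.outer(s_a, p_a)
    noise = _spatial_noise(rng, clean.shape, config.noise_sd, config.spatial_corr) \
        if config.noise_sd > 0 else 0.0
    scr_rng = np.random.default_rng(rng.integers(2**31))
    aro_centered = np.array([float(lab.loc[sid, "aro_mean"]) - 5.0
                             for sid in design.events["stimulus_id"]])
    scr_amps = (config.scr_amp_slope * aro_centered
                + config.scr_amp_noise_sd * scr_rng.standard_normal(n_trials))
    truth = GroundTruth(pattern_valence=p_v, pattern_arousal=p_a,
                        amp_valence=s_v, amp_arousal=s_a,
                        clean_patterns=clean,
                        incongruent_ids=frozenset(incongruent_ids),
                        scr_amplitudes=scr_amps)
    return clean + noise, truth


def gen_bold(design: TrialDesign, trial_patterns: np.ndarray,
             hrf: Kernel | None = None, noise_sd: float = 0.0,
             drift_sd: float = 0.0,
             seed: int | np.random.Generator = 0) -> list[np.ndarray]:
    """Forward-model BOLD runs from per-trial voxel amplitudes.

    ``trial_patterns`` holds one amplitude pattern per design row (all
    formats, timeline order). Each run's signal is the sum over its trials
    of amplitude x (HRF (*) trial boxcar), sampled at the TR grid, plus
    optional linear/quadratic drift and white noise.

    Returns one (n_volumes, n_voxels) matrix per run.
    """
    rng = np.random.default_rng(seed)
    if hrf is None:
        hrf = hrf_kernel(dt=0.1, stim_duration=0.0)
    dt = hrf.dt
    nvol = design.n_volumes_per_run
    vol_idx = np.rint(np.arange(nvol) * design.tr / dt).astype(int)
    n_fine = max(int(round(design.run_length_s / dt)), int(vol_idx[-1]) + 1)
    trial_patterns = np.atleast_2d(np.asarray(trial_patterns, float))
    if len(trial_patterns) != len(design.events):
        raise ValueError("one pattern row per design trial required")

    runs = []
    for r in range(design.n_runs):
        mask = (design.events["run"] == r).to_numpy()
        ev = design.events[mask]
        if np.any(ev["onset"].to_numpy() + ev["duration"].to_numpy()
                  > design.run_length_s):
            raise ValueError("trial extends outside run bounds")
        regs = np.zeros((mask.sum(), nvol))
        for k, (_, row) in enumerate(ev.iterrows()):
            box = np.zeros(n_fine)
            i0 = int(round(row["onset"] / dt))
            i1 = int(round((row["onset"] + row["duration"]) / dt))
            box[i0:i1] = 1.0
            regs[k] = hrf.convolve(box)[vol_idx]
        signal = regs.T @ trial_patterns[mask]
        if drift_sd > 0:
            t = np.linspace(-1, 1, nvol)
            coefs = rng.standard_normal((3, signal.shape[1])) * drift_sd
            signal = signal + np.polynomial.legendre.legval(
                t, coefs, tensor=True).reshape(signal.shape)
        if noise_sd > 0:
            signal = signal + noise_sd * rng.standard_normal(signal.shape)
        runs.append(signal)
    return runs


def gen_scr(design: TrialDesign, event_amplitudes: np.ndarray,
            config: SyntheticConfig,
            seed: int | np.random.Generator = 0) -> list[np.ndarray]:
    """Raw skin-conductance traces, one per run.

    Each image presentation (any format) launches a canonical SCR scaled
    by its planted amplitude; slow drift (smoothed random walk, scale
    ``drift_sd``) and white measurement noise are added on top.
    """
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    if fs < 20:
        raise ValueError("sampling_rate must be >= 20 Hz")
    kern = scr_canonical(dt=1.0 / fs)
    n_samp = int(round(design.run_length_s * fs))
    event_amplitudes = np.asarray(event_amplitudes, float)
    if len(event_amplitudes) != len(design.events):
        raise ValueError("one amplitude per design trial required")

    traces = []
    for r in range(design.n_runs):
        mask = (design.events["run"] == r).to_numpy()
        impulses = np.zeros(n_samp)
        for amp, (_, row) in zip(event_amplitudes[mask],
                                 design.events[mask].iterrows()):
            impulses[int(round(row["onset"] * fs))] += amp
        trace = kern.convolve(impulses)
        if config.drift_sd > 0:
            walk = np.cumsum(rng.standard_normal(n_samp))
            walk = gaussian_filter1d(walk, sigma=5.0 * fs)
            walk -= walk[0]
            sd = walk.std()
            if sd > 0:
                walk *= config.drift_sd / sd
            trace = trace + walk
        if config.scr_noise_sd > 0:
            trace = trace + config.scr_noise_sd * rng.standard_normal(n_samp)
        traces.append(trace)
    return traces
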