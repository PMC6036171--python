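import numpy as np
import pandas as pd
import pytest

from affectstates import synthetic
from affectstates.design import TrialDesign
from affectstates.lss import BetaSeries


@pytest.fixture(scope="session")
def pool():
    """A 400-stimulus boomerang pool with labels."""
    return synthetic.gen_stimulus_pool(400, coupling=0.5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_design(onsets, trial_types=None, run=0, tr=2.0, tail=40.0,
                durations=2.0):
    """Build a bare TrialDesign from onset times (single run)."""
    onsets = np.asarray(onsets, float)
    n = len(onsets)
    if trial_types is None:
        trial_types = ["extrinsic"] * n
    ev = pd.DataFrame({
        "onset": onsets,
        "duration": durations,
        "trial_type": trial_types,
        "stimulus_id": np.arange(n),
        "run": run,
        "iti": 4.0,
    })
    return TrialDesign(events=ev, tr=tr, run_length_s=float(onsets[-1] + tail))


def make_betas(x, subject=0, modality="GM", ids=None):
    x = np.atleast_2d(x)
    if ids is None:
        ids = np.arange(x.shape[0])
    return BetaSeries(data=x, modality=modality, stimulus_ids=np.asarray(ids),
                      subject=subject)


def planted_group(n_subjects, n_trials, n_voxels, amp, noise_sd=1.0,
                  spatial_corr=0.0, incongruent=frozenset(), seed=0):
    """Subjects sharing planted valence/arousal patterns; returns
    (betas per subject, labels_v, labels_a per subject, patterns)."""
    rng = np.random.default_rng(seed)
    pv, pa = synthetic.gen_encoding_patterns(n_voxels, rng,
                                             spatial_corr=spatial_corr)
    out = []
    for s in range(n_subjects):
        lab_v = np.where(rng.random(n_trials) < 0.5, 1, -1)
        lab_a = np.where(rng.random(n_trials) < 0.5, 1, -1)
        # guarantee both classes exist
        lab_v[:2], lab_v[2:4] = 1, -1
        lab_a[:2], lab_a[2:4] = -1, 1
        s_v = lab_v.astype(float) * amp
        s_a = lab_a.astype(float) * amp
        for j in incongruent:
            s_v[j] *= -1
            s_a[j] *= -1
        clean = np.outer(s_v, pv) + np.outer(s_a, pa)
        noise = synthetic._spatial_noise(rng, clean.shape, noise_sd,
                                         spatial_corr) if noise_sd else 0.0
        out.append((make_betas(clean + noise, subject=s), lab_v, lab_a))
    return out, (pv, pa)
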