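import numpy as np
import pytest
from scipy import stats

from affectstates import synthetic
from affectstates.kernels import hrf_kernel, scr_canonical, scr_peak_latency
from conftest import make_design


@pytest.fixture
def small_design():
    return make_design([10.0, 60.0, 110.0, 160.0],
                       ["extrinsic", "extrinsic", "extrinsic", "intrinsic"])


def _config(**kw):
    defaults = dict(n_subjects=1, n_extrinsic=3, n_intrinsic=1, n_voxels=10,
                    n_runs=1, noise_sd=0.0, drift_sd=0.0, scr_noise_sd=0.0,
                    scr_amp_noise_sd=0.0)
    defaults.update(kw)
    return synthetic.SyntheticConfig(**defaults)


@pytest.fixture
def small_catalog():
    pool = synthetic.gen_stimulus_pool(20, seed=5)
    return pool.iloc[:4].assign(stimulus_id=[0, 1, 2, 3]).reset_index(drop=True)


def test_zero_noise_betas_equal_planted_model(small_catalog, small_design):
    cfg = _config()
    betas, truth = synthetic.gen_subject_betas(small_catalog, small_design, cfg,
                                               seed=3)
    expected = (np.outer(truth.amp_valence, truth.pattern_valence)
                + np.outer(truth.amp_arousal, truth.pattern_arousal))
    assert np.allclose(betas, expected)
    assert np.allclose(betas, truth.clean_patterns)


def test_incongruent_stimulus_projects_opposite_to_label(small_catalog,
                                                         small_design):
    cfg = _config(incongruent_fraction=0.5, amplitude_mode="signed")
    betas, truth = synthetic.gen_subject_betas(small_catalog, small_design, cfg,
                                               seed=3)
    lab = small_catalog.set_index("stimulus_id")
    assert truth.incongruent_ids
    for k, sid in enumerate(small_design.events["stimulus_id"]):
        proj = betas[k] @ truth.pattern_valence
        sign = np.sign(lab.loc[sid, "val_label"])
        if sid in truth.incongruent_ids:
            assert np.sign(proj) == -sign
        else:
            assert np.sign(proj) == sign


def test_too_few_voxels_rejected(small_catalog, small_design):
    with pytest.raises(ValueError, match="n_voxels"):
        _config(n_voxels=2)


def test_bold_is_linear_in_trials(small_design, small_catalog):
    hrf = hrf_kernel(dt=0.1, stim_duration=0.0)
    amps = np.array([[1.0], [0.0], [0.0], [0.0]])
    single = synthetic.gen_bold(small_design, amps, hrf=hrf)[0]
    amps2 = np.array([[1.0], [2.0], [0.0], [0.0]])
    both = synthetic.gen_bold(small_design, amps2, hrf=hrf)[0]
    shift = np.array([[0.0], [2.0], [0.0], [0.0]])
    other = synthetic.gen_bold(small_design, shift, hrf=hrf)[0]
    assert np.allclose(both, single + other, atol=1e-12)
    # single unit trial: trace equals the convolved regressor, peaking 5-8 s
    peak_t = np.argmax(single[:, 0]) * small_design.tr - 10.0
    assert 4.0 <= peak_t <= 8.0


def test_bold_rejects_out_of_bounds_onsets(small_catalog):
    d = make_design([10.0, 20.0], tail=5.0)
    d.events.loc[1, "onset"] = d.run_length_s - 1.0
    with pytest.raises(ValueError, match="bounds"):
        synthetic.gen_bold(d, np.ones((2, 1)))


def test_scr_zero_amplitude_trace_is_drift_only(small_design):
    cfg = _config(drift_sd=0.0, scr_noise_sd=0.0)
    traces = synthetic.gen_scr(small_design, np.zeros(4), cfg, seed=1)
    assert np.allclose(traces[0], 0.0)


def test_scr_unit_event_peaks_at_canonical_latency():
    d = make_design([5.0], tail=30.0)
    cfg = _config(n_extrinsic=1, n_intrinsic=0, drift_sd=0.0, scr_noise_sd=0.0)
    trace = synthetic.gen_scr(d, np.array([1.0]), cfg, seed=0)[0]
    peak_t = np.argmax(trace) / cfg.sampling_rate - 5.0
    assert peak_t == pytest.approx(scr_peak_latency(), abs=0.05)


def test_scr_runs_have_independent_drift(small_catalog):
    d2 = make_design([10.0, 60.0], run=0)
    ev2 = d2.events.copy()
    ev2["run"] = 1
    import pandas as pd
    from affectstates.design import TrialDesign
    d = TrialDesign(events=pd.concat([d2.events, ev2], ignore_index=True),
                    tr=2.0, run_length_s=d2.run_length_s)
    cfg = _config(n_extrinsic=2, n_intrinsic=0, n_runs=2, drift_sd=0.3,
                  scr_noise_sd=0.0)
    traces = synthetic.gen_scr(d, np.zeros(4), cfg, seed=9)
    assert len(traces) == 2
    assert not np.allclose(traces[0], traces[1])


def test_seeded_regeneration_is_bit_identical(small_catalog, small_design):
    cfg = _config(noise_sd=1.0)
    a, _ = synthetic.gen_subject_betas(small_catalog, small_design, cfg, seed=42)
    b, _ = synthetic.gen_subject_betas(small_catalog, small_design, cfg, seed=42)
    assert np.array_equal(a, b)


def test_oracle_discriminant_matches_closed_form():
    """Planted d'=2 signed amplitudes: projecting held-out patterns onto the
    true valence pattern classifies with accuracy Phi(d'/2) = 0.841."""
    rng = np.random.default_rng(0)
    n, p = 4000, 50
    pv, pa = synthetic.gen_encoding_patterns(p, 1)
    amp = synthetic.amplitude_for_dprime(2.0, 1.0)
    lab = np.where(rng.random(n) < 0.5, 1, -1)
    lab_a = np.where(rng.random(n) < 0.5, 1, -1)
    x = (np.outer(lab * amp, pv) + np.outer(lab_a * amp, pa)
         + rng.standard_normal((n, p)))
    acc = np.mean(np.sign(x @ pv) == lab)
    assert acc == pytest.approx(stats.norm.cdf(1.0), abs=0.02)


def test_spatial_noise_preserves_marginal_scale(rng):
    smooth = synthetic._spatial_noise(rng, (200, 500), sd=2.0, corr_len=5.0)
    assert smooth.std() == pytest.approx(2.0, rel=0.05)
    # neighbouring features correlate, distant ones do not
    lag1 = np.mean([np.corrcoef(smooth[:, i], smooth[:, i + 1])[0, 1]
                    for i in range(0, 100, 10)])
    lag50 = np.mean([np.corrcoef(smooth[:, i], smooth[:, i + 50])[0, 1]
                     for i in range(0, 100, 10)])
    assert lag1 > 0.8 and abs(lag50) < 0.2
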