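import pytest

from driftdecode import TaskConfig, generate_experiment, align_to_trials
from driftdecode.preprocess import preprocess_day

TAU_MAP = {
    "context": 7.3,
    "motor": 1.9,
    "post_decision_outcome": 2.2,
    "post_trial_outcome": 35.7,
}


@pytest.fixture(scope="session")
def tau_map():
    return dict(TAU_MAP)


@pytest.fixture(scope="session")
def small_config():
    return TaskConfig(n_trials=40, n_cells=20, n_days=3, turnover_prob=0.0)


@pytest.fixture(scope="session")
def small_bundle(small_config, tau_map):
    return generate_experiment(small_config, tau_map, seed=7)


@pytest.fixture(scope="session")
def small_tensors(small_bundle, small_config):
    """Preprocessed, trial-aligned ΔF/F tensors per day of the small bundle."""
    out = {}
    for dd in small_bundle.days:
        dff, alphas = preprocess_day(dd.f_soma, dd.f_neuropil)
        tt = align_to_trials(dff, dd.trials,
                             window=(0.0, small_config.trial_duration_s),
                             frame_rate_hz=small_config.frame_rate_hz, day=dd.day)
        out[dd.day] = tt
    return out
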