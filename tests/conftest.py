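import numpy as np
import pytest

import ridemvpa as rm


@pytest.fixture(scope="session")
def montage60():
    return rm.make_montage(60, "fibonacci-sphere")


@pytest.fixture(scope="session")
def nogo_session():
    """216-trial Nogo-like session with the default two-source generator."""
    design = rm.TaskDesign(n_trials=216, go_proportion=0.0,
                           congruent_proportion=0.5, n_blocks=6)
    trials = rm.generate_trial_table(design, seed=0)
    trials = rm.simulate_behaviour(trials, seed=1)
    tp = rm.TruthParams(srate_hz=250.0, epoch_window_ms=(-500.0, 1200.0))
    epochs, truth = rm.simulate_epochs(trials, tp, seed=2)
    return epochs, truth


@pytest.fixture(scope="session")
def nogo_decomposition(nogo_session):
    epochs, truth = nogo_session
    result = rm.ride_decompose(epochs, rm.RideConfig())
    return epochs, truth, result


@pytest.fixture(scope="session")
def small_epochs(montage60):
    """Tiny clean epochs for fast preprocessing tests."""
    rng = np.random.default_rng(3)
    design = rm.TaskDesign(n_trials=16, go_proportion=0.5,
                           congruent_proportion=0.5, n_blocks=2)
    trials = rm.generate_trial_table(design, seed=0)
    n_t = 250
    srate = 250.0
    times = -300.0 + np.arange(n_t) * 1000.0 / srate
    data = rng.standard_normal((16, 60, n_t)) * 5.0
    return rm.Epochs(data=data, srate_hz=srate, times_ms=times,
                     montage=montage60, trials=trials)
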