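import numpy as np
import pandas as pd
import pytest

from pupilbias import ddm, synth
from pupilbias.preproc import PreprocConfig, PupilTrace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_yesno_dataset():
    """One yes/no subject with coupling, behavior and a pupil trace."""
    spec = synth.TaskSpec(
        task_kind="yesno",
        n_subjects=1,
        trials_per_subject=240,
        loudness_levels=(-20.0,),
        sampling_rate_hz=100.0,
    )
    params = ddm.DDMParams(v=1.0, a=1.5, t0=0.4)
    coupling = synth.ArousalCouplingSpec(bias_base=-0.5, coupling_gamma=1.0)
    trials, truths, traces = synth.generate_dataset(spec, params, coupling, seed=7)
    return {
        "spec": spec,
        "trials": trials,
        "truth": truths["s00"],
        "trace": traces["s00"],
        "coupling": coupling,
    }


@pytest.fixture()
def flat_trace():
    """Constant trace helper for preprocessing edge cases."""
    def make(value=1000.0, n=2000, rate=100.0, mask=None, events=()):
        return PupilTrace(
            np.full(n, float(value)), rate, mask, list(events)
        )

    return make


@pytest.fixture()
def preproc_config():
    return PreprocConfig(
        scalar_window=("stimulus", 0.23, 0.50), target_rate_hz=50.0, n_bins=5
    )


@pytest.fixture(scope="session")
def simple_trial_frame():
    """Tiny behavioral table for fit plumbing tests."""
    rng = np.random.default_rng(3)
    n = 400
    signal = np.tile([0, 1], n // 2)
    p = ddm.DDMParams(v=1.0, a=1.0, t0=0.3)
    drifts = np.where(signal == 1, 1.0, -1.0)
    ch, rt = ddm.simulate_ddm(p, drifts=drifts, seed=9)
    return pd.DataFrame({"signal": signal, "choice": ch, "rt": rt})
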