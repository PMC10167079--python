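import numpy as np
import pytest

from erpmvpa.simgen import EpochSet

MASTER_SEED = 1234


def make_epochs(data, sfreq=256.0, t0=None, labels=None, correct=None,
                rt=None, pid="p0", group="g0"):
    """Minimal EpochSet around a raw (trials, channels, samples) array."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_samp = data.shape
    if t0 is None:
        t0 = 0.0
    times = t0 + np.arange(n_samp) / sfreq
    if labels is None:
        labels = np.array(["congruent", "incongruent"]
                          )[np.arange(n_trials) % 2]
    if correct is None:
        correct = np.ones(n_trials, dtype=bool)
    if rt is None:
        rt = np.full(n_trials, 500.0)
    return EpochSet(data=data, sfreq=sfreq, times=times,
                    trial_labels=np.asarray(labels), correctness=correct,
                    rt=np.asarray(rt, dtype=float), participant_id=pid,
                    group_label=group,
                    ch_names=[f"ch{i}" for i in range(n_ch)])


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)
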