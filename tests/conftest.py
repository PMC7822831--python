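import numpy as np
import pytest

from eegstates.montage import make_montage
from eegstates.topographies import orthogonal_topographies


@pytest.fixture(scope="session")
def montage():
    return make_montage()


@pytest.fixture(scope="session")
def templates6(montage):
    """The six planted group-level templates (orthogonal, unit-norm)."""
    return orthogonal_topographies(montage, 6)


@pytest.fixture(scope="session")
def recovery_study():
    """The seeded 4-participant synthetic study used by the recovery checks.

    Rendered task blocks are capped at 30 s (rest 90 s) so the whole study
    stays desk-sized; built once per session.
    """
    from eegstates.synth import StudyConfig, generate_study

    cfg = StudyConfig(n_participants=4, rest_seconds=90.0, max_render_seconds=30.0)
    return generate_study(cfg, seed=0)


@pytest.fixture(scope="session")
def recovery_epochs(recovery_study):
    from eegstates.pipeline import preprocess_study

    return preprocess_study(recovery_study)


@pytest.fixture(scope="session")
def recovery_micro(recovery_epochs):
    from eegstates.pipeline import RunConfig, microstate_stage

    cfg = RunConfig(seed=0, n_participants=4, restarts=10, run_select_k=False)
    return microstate_stage(recovery_epochs["broadband"], cfg)


def tone_recording(freq, amp, seconds=20.0, srate=500.0, n_channels=63, names=None):
    """Recording with the same pure tone on every channel pair (+/-)."""
    from eegstates.montage import Recording, make_montage

    t = np.arange(int(seconds * srate)) / srate
    tone = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(tone, (n_channels, 1))
    # alternate sign so the average reference does not null the tone
    data[1::2] *= -1
    names = names if names is not None else make_montage().channels[:n_channels]
    return Recording(data=data, srate=srate, channel_names=tuple(names))
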