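import numpy as np
import pytest

import figground as fg

SESSION_SEED = 20230


@pytest.fixture(scope="session")
def sfg_spec():
    return fg.SFGStimulusSpec()

@pytest.fixture(scope="session")
def rendered_session(sfg_spec):
    """One full 120-trial figure-ground session with audio, shared by the
    energy-control, electrodogram and acceptance tests (synthesis is the
    expensive step)."""
    return fg.generate_sfg_session(sfg_spec, n_trials=120, seed=SESSION_SEED)


@pytest.fixture(scope="session")
def encoded_session(rendered_session):
    """ACE electrodograms of the shared session."""
    return [fg.ace_encode(s.waveform) for s in rendered_session]
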