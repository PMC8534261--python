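import numpy as np
import pandas as pd
import pytest

from limbid.records import DEFAULT_FREQUENCIES, PAIRS, SessionRecord, StudyData


def compose_channels(limb, fingers, n_freq=25):
    """Additively compose the 10 channel spectra from latent spectra.

    ``limb`` and each entry of ``fingers`` may be scalars (flat
    spectra) or arrays of length ``n_freq``.
    """
    limb = np.broadcast_to(np.asarray(limb, dtype=float), (n_freq,))
    fing = [np.broadcast_to(np.asarray(f, dtype=float), (n_freq,)) for f in fingers]
    rows = []
    for a, b in PAIRS:
        rows.append(limb + fing[b - 1] if a == 0 else fing[a - 1] + fing[b - 1])
    return np.stack(rows)


def make_session(limb, fingers, subject_id="S01", day_index=1, repeat_index=1):
    """Session with noiseless additively-composed channels."""
    return SessionRecord(
        subject_id=subject_id,
        day_index=day_index,
        repeat_index=repeat_index,
        frequencies=DEFAULT_FREQUENCIES,
        channels=compose_channels(limb, fingers),
    )


def study_from_sessions(sessions):
    meta = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in sessions],
            "day_index": [s.day_index for s in sessions],
            "repeat_index": [s.repeat_index for s in sessions],
        }
    )
    return StudyData(
        channels=np.stack([s.channels for s in sessions]),
        meta=meta,
        frequencies=sessions[0].frequencies,
    )


@pytest.fixture
def flat_session():
    """limb=100, fingers=(50, 60, 70, 80): channel (0,1)=150, (1,2)=110, ..."""
    return make_session(100.0, (50.0, 60.0, 70.0, 80.0))


@pytest.fixture(scope="session")
def small_study():
    """Nominal 6-subject, 3-day, 5-repeat study with default generator."""
    from limbid.synth import simulate_study

    data, truths = simulate_study(6, 3, 5, seed=7)
    return data, truths
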