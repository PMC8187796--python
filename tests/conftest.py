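"""Shared fixtures.

The EMG fixture chain (generate → filter → unmix → envelope → train) is
the slow part of the suite, so it is built once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from prosmile.emg import (
    bandpass,
    frame_labels_from_track,
    rms_envelope,
    train_smile_classifier,
    unmix,
)
from prosmile.synth import (
    SyntheticEMGConfig,
    SyntheticSessionConfig,
    generate_case_table,
    generate_emg,
)


@pytest.fixture(scope="session")
def emg_world():
    """A clean synthetic recording with its truth track and trained detector."""
    config = SyntheticEMGConfig(duration_s=120.0, mixing_seed=7, noise_seed=11)
    recording, truth = generate_emg(config)
    filtered = bandpass(recording)
    components, unmixing = unmix(filtered, seed=0)
    features = rms_envelope(components, recording.sample_rate)
    labels = frame_labels_from_track(truth, features.frame_times, features.frame_ms)
    model = train_smile_classifier(
        features,
        labels,
        seed=0,
        unmixing=unmixing,
        channel_mean=recording.samples.mean(axis=0),
    )
    return {
        "config": config,
        "recording": recording,
        "truth": truth,
        "filtered": filtered,
        "components": components,
        "unmixing": unmixing,
        "features": features,
        "labels": labels,
        "model": model,
    }


@pytest.fixture(scope="session")
def cases36():
    """36-case table matching the published smile × PB cell counts."""
    return generate_case_table(36, seed=0)


@pytest.fixture(scope="session")
def big_study_cases():
    """~10,000 chain-generated cases under the calibrated defaults."""
    from prosmile.synth import generate_study

    config = SyntheticSessionConfig(
        seed=42, n_per_group=250, sessions_per_group={"ASD": 10, "TD": 10}
    )
    _, cases = generate_study(config)
    return cases
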