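import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import stairhip as sh
from stairhip import templates as tpl

settings.register_profile("ci", derandomize=True, max_examples=30,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def templates():
    return tpl.default_templates()


@pytest.fixture(scope="session")
def subject():
    return sh.Subject.from_anthropometry(1.74, 81.6)


@pytest.fixture(scope="session")
def noisy_trial():
    """One default-noise synthetic trial."""
    return sh.generate_trial(sh.sample_subject(4), seed=2)


@pytest.fixture(scope="session")
def clean_trial():
    """One noise-free synthetic trial."""
    return sh.generate_trial(sh.sample_subject(4), seed=2,
                             noise_sd={"all": 0.0})


@pytest.fixture(scope="session")
def small_cohort():
    """Four default-noise subjects (shared across detector/pipeline tests)."""
    return sh.generate_cohort(n_subjects=4, seed=11)


@pytest.fixture(scope="session")
def clean_templates():
    """Default templates with all per-subject jitter disabled."""
    return dataclasses.replace(tpl.default_templates(),
                               amplitude_jitter_sd=0.0,
                               offset_jitter_deg=0.0,
                               offset_jitter_nmkg=0.0)


def match_events(detected, truth, max_gap):
    """Per-truth-event detection error (NaN when nothing within max_gap)."""
    detected = np.asarray(detected, dtype=float)
    out = []
    for t0 in truth:
        if detected.size and np.min(np.abs(detected - t0)) < max_gap:
            out.append(detected[np.argmin(np.abs(detected - t0))] - t0)
        else:
            out.append(np.nan)
    return np.asarray(out)
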