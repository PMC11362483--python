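"""Shared fixtures: a small synthetic study and the full default study.

All fixtures are generated programmatically at session start from fixed
seeds; nothing is read from disk.
"""

from __future__ import annotations

import logging

import pytest

import namingnorms as nn

logging.getLogger("namingnorms").setLevel(logging.ERROR)


SMALL_DESIGN = nn.StudyDesign(
    n_participants=12,
    n_lists=8,
    list_length=10,
    n_objects=20,
    images_per_object=4,
    min_lists_per_participant=4,
    max_lists_per_participant=8,
    mean_lists_target=5.5,
    starting_lists=(0, 4),
)


@pytest.fixture(scope="session")
def small_study() -> nn.SimulatedStudy:
    """A 20-object, 12-participant study: fast, with every noise category."""
    return nn.simulate_study(design=SMALL_DESIGN, seed=7)


@pytest.fixture(scope="session")
def default_study() -> nn.SimulatedStudy:
    """The full default study: 800 images, 60 participants, ~25k trials."""
    return nn.simulate_study(seed=0)


@pytest.fixture(scope="session")
def default_norms(default_study):
    """Coded responses, trimmed RTs and compiled norms for the default study."""
    coded = nn.code_trials(default_study.trials, default_study.resources)
    retained, trim_report = nn.trim_rts(coded)
    retained, flagged = nn.participant_screen(retained)
    rt_means = nn.image_mean_rt(retained)
    norms, summary = nn.compile_image_norms(coded, default_study.lexicon, rt_means)
    return {
        "coded": coded,
        "trim_report": trim_report,
        "flagged": flagged,
        "rt_means": rt_means,
        "norms": norms,
        "summary": summary,
    }
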