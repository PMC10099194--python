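"""Shared fixtures: all inputs are generated programmatically at test time."""

import numpy as np
import pytest

from somnoscope.synthetic import (
    BehaviorScript,
    RenderParams,
    generate_behavior_script,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_script() -> BehaviorScript:
    """Hand-built script: one eye closure, one yawn, on 96 frames."""
    return BehaviorScript(
        events=[(10, 20, "eye_closure"), (50, 30, "yawn")], total_frames=96
    )


@pytest.fixture()
def render_params() -> RenderParams:
    return RenderParams(seed=7)


@pytest.fixture()
def random_script() -> BehaviorScript:
    return generate_behavior_script(
        800, {"eye_closure": 0.004, "yawn": 0.002}, seed=42
    )
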