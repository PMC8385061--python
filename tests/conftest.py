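"""Shared fixtures: small synthetic scenes that keep the full
buffer/odor/buffer structure but run at a reduced frame rate so tracking
stays fast."""

from __future__ import annotations

import numpy as np
import pytest

from wormnai import StimulusProtocol, SyntheticSceneSpec, generate_stack


@pytest.fixture(scope="session")
def mini_protocol() -> StimulusProtocol:
    """Standard 10/20/30 s intervals at 2 frames/s: 120 frames, the
    10-frame baseline spans 5 s of the pre-stimulus buffer, and both
    10-s activation windows fit."""
    return StimulusProtocol(frame_rate=2.0)


@pytest.fixture(scope="session")
def responder_scene(mini_protocol):
    """One static, noise-free responding animal."""
    spec = SyntheticSceneSpec(
        arena_size=(96, 96),
        n_animals=1,
        protocol=mini_protocol,
        noise_sd=0.0,
        responders=(True,),
        rng_seed=11,
    )
    stack, gt = generate_stack(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def quiet_scene(mini_protocol):
    """One static, noise-free non-responding animal."""
    spec = SyntheticSceneSpec(
        arena_size=(96, 96),
        n_animals=1,
        protocol=mini_protocol,
        noise_sd=0.0,
        responders=(False,),
        rng_seed=12,
    )
    stack, gt = generate_stack(spec)
    return spec, stack, gt


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
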