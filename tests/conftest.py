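"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from fingerctx import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def small_cfg():
    return GeneratorConfig(seed=12345, n_channels=24, fraction_failed=0.05)


@pytest.fixture(scope="session")
def two_context_session(small_cfg):
    """Normal + spring session, 40 trials per block, 24 channels."""
    return generate_session(small_cfg, [("normal", 40), ("spring", 40)])


@pytest.fixture(scope="session")
def decoding_session():
    """Larger session for offline decoding (needs >= 10 normal trials)."""
    cfg = GeneratorConfig(seed=777, n_channels=32)
    return generate_session(cfg, [("normal", 60), ("spring", 60)])


@pytest.fixture(scope="session")
def multi_context_session():
    """Four-context session for population-geometry analyses."""
    cfg = GeneratorConfig(seed=4242, n_channels=48)
    return generate_session(
        cfg, [("normal", 80), ("spring", 80), ("wrist", 80), ("band", 80)])


@pytest.fixture(scope="session")
def trained_loop():
    """Encoder + Kalman decoder trained in the matched (normal) condition."""
    from fingerctx import LinearEncoder
    from fingerctx.pipeline import train_decoder_from_encoder

    cfg = GeneratorConfig(seed=99, n_channels=32)
    encoder = LinearEncoder.from_config(cfg, noise_sd=0.05)
    decoder = train_decoder_from_encoder(encoder, seed=1)
    return encoder, decoder
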