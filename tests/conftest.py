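"""Shared fixtures: bundled presets and small synthetic schemes."""

import numpy as np
import pytest

from navkit import (
    HHChannelSpec,
    HHGate,
    MarkovSchemeSpec,
    MarkovTransition,
    RateLaw,
    TemperatureSpec,
    load_channel,
)


@pytest.fixture(scope="session")
def markov():
    return load_channel("nav15_markov")


@pytest.fixture(scope="session")
def hh_row_h():
    return load_channel("nav15_hh_row_h")


@pytest.fixture(scope="session")
def hh_variant_a():
    return load_channel("nav15_hh_variant_a")


@pytest.fixture(scope="session")
def hh_variant_b():
    return load_channel("nav15_hh_variant_b")


@pytest.fixture(scope="session")
def squid():
    return load_channel("hh_squid_original")


@pytest.fixture
def two_state_constant():
    """Symmetric two-state scheme with constant rate c = 0.5 ms^-1."""
    c = RateLaw("constant", {"A": 0.5})
    return MarkovSchemeSpec(
        states=("A", "B"),
        open_state="B",
        transitions=(
            MarkovTransition("A", "B", c),
            MarkovTransition("B", "A", c),
        ),
        gbar=0.1,
        E_rev=65.0,
        temperature=TemperatureSpec(T=20.0, T_base=20.0),
        name="two_state",
    )


@pytest.fixture
def single_gate_hh():
    """One first-order gate with alpha = beta = 0.5 ms^-1."""
    half = RateLaw("constant", {"A": 0.5})
    return HHChannelSpec(
        gates=(HHGate("x", 1, half, half),),
        gbar=0.1,
        E_rev=65.0,
        temperature=TemperatureSpec(T=20.0, T_base=20.0),
        name="single_gate",
    )
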