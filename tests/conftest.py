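from __future__ import annotations

import random

import pytest

from dicomflow.broker import MemoryBroker
from dicomflow.fixtures import make_scenario
from dicomflow.runtime import StackConfig, build_stack
from dicomflow.storage import MemoryBundleStore


@pytest.fixture
def rng():
    return random.Random(20240101)


@pytest.fixture
def store():
    return MemoryBundleStore()


@pytest.fixture
def broker():
    return MemoryBroker()


@pytest.fixture(scope="session")
def scenarios():
    """The three preset scenarios, generated once per session."""
    return {name: make_scenario(name, seed=7) for name in
            ("single_modality", "multi_modality", "sct")}


@pytest.fixture
def stack_factory(tmp_path):
    """Build an all-in-one stack for a scenario (in-memory backends)."""

    def factory(scenario, *, config: StackConfig | None = None, **kwargs):
        cfg = config or StackConfig(scratch_root=tmp_path / "scratch")
        return build_stack(cfg, flows=list(scenario.flows), **kwargs)

    return factory
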