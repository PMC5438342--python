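"""Shared fixtures: one study-scale and one small synthetic dataset, generated
once per session, plus the downstream products the stages derive from them."""
from __future__ import annotations

import pytest

import regulonexo as rx


@pytest.fixture(scope="session")
def config():
    return rx.RunConfig(seed=42)


@pytest.fixture(scope="session")
def paper_ds(config):
    return rx.generate_scenario(config, preset="paper_scale")


@pytest.fixture(scope="session")
def paper_peaks(paper_ds, config):
    return rx.call_peaks(paper_ds.chip, config)


@pytest.fixture(scope="session")
def paper_de(paper_ds):
    return rx.run_diffexpr(paper_ds.counts)


@pytest.fixture(scope="session")
def paper_regulon(paper_peaks, paper_ds, paper_de):
    return rx.build_regulon(paper_peaks, paper_ds.annotation, paper_de)


@pytest.fixture(scope="session")
def small_ds():
    return rx.generate_scenario(rx.RunConfig(seed=1), preset="small")


@pytest.fixture(scope="session")
def small_peaks(small_ds):
    return rx.call_peaks(small_ds.chip, rx.RunConfig(seed=1))
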