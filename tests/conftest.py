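"""Shared fixtures: packaged config, stage outputs and the multi-seed
trend report (session-scoped because they are the expensive computations)."""

import pytest

from tendonheal import interface_io, protocols


@pytest.fixture(scope="session")
def config():
    return interface_io.load_config()


@pytest.fixture(scope="session")
def stage_inputs(config):
    """Strain/alignment/synthesis outputs for the four canonical conditions.

    Maps condition name -> (tendon profile, cell profile, steady-state S,
    mean strain, synthesis rate).
    """
    return {c.name: protocols.condition_cell_inputs(c, config)
            for c in protocols.CONDITIONS}


@pytest.fixture(scope="session")
def trend_report(config):
    """Three-seed, 42-day run of all four conditions on the scaled
    (0.5 x 1 mm) test wound."""
    return protocols.reproduce_trends([1, 2, 3], days=42.0,
                                      wound_length_mm=0.5, config=config)
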