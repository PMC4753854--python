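"""Shared fixtures: a moderate-scale cassette layout with its template,
well map and parameters, reused across test modules to keep runtime down."""

import numpy as np
import pytest

from corebreak import CassetteLayout, generate_template
from corebreak.pipeline import params_for_layout
from corebreak.wells import find_wells

SCALE = 0.35


@pytest.fixture(scope="session")
def layout():
    return CassetteLayout.default(SCALE)


@pytest.fixture(scope="session")
def params(layout):
    return params_for_layout(layout)


@pytest.fixture(scope="session")
def template(layout):
    return generate_template(layout, seed=1, jitter_px=2.0, flare=0.05)


@pytest.fixture(scope="session")
def wellmap(template, params):
    return find_wells(template, params)
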