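"""Shared fixtures: seeded synthetic worlds at two sizes."""

import numpy as np
import pytest

from lesim import drivers as dv
from lesim import synthdata as sd


@pytest.fixture(scope="session")
def spec200():
    return sd.SynthSpec(rows=200, cols=200, seed=7)


@pytest.fixture(scope="session")
def world200(spec200):
    """A 200x200 landscape pair used by the simulation-scale tests."""
    t0, t1 = sd.synth_landscape(spec200)
    return t0, t1


@pytest.fixture(scope="session")
def stack200(spec200, world200):
    t0, _ = world200
    return sd.synth_drivers(spec200, t0)


@pytest.fixture(scope="session")
def class_weights200(world200, stack200):
    """Fitted signed factor weights per class on the 200x200 world."""
    _, t1 = world200
    out = {}
    for code in t1.codes:
        res = dv.fit_class_weights(t1, stack200, code, fraction=0.05, seed=3)
        out[code] = {
            row["factor"]: (row["weight"], row["sign"])
            for _, row in res.table.iterrows()
            if row["weight"] > 0
        }
    return out


@pytest.fixture(scope="session")
def spec60():
    return sd.SynthSpec(rows=60, cols=60, seed=11, n_towns=2, unit_cells=6)


@pytest.fixture(scope="session")
def world60(spec60):
    """A small landscape pair for fast unit tests."""
    return sd.synth_landscape(spec60)
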