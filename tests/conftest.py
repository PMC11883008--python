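"""Shared fixtures: heavy simulations are session-scoped so the damage and
mapping checks reuse one 50k-read experiment."""

from __future__ import annotations

import numpy as np
import pytest

import sedapop as sp
from sedapop.experiments import run_mapped_simulation


@pytest.fixture(scope="session")
def mito_refs():
    """One 16 kb mitogenome-sized reference (matches the experiment panels)."""
    return sp.generate_references(101, [("mt", 16000)], 0.0)


@pytest.fixture(scope="session")
def damaged_sim():
    """50k single-end reads with terminal deamination (d_max=0.04, decay 0.3)
    and 1e-3 sequencing error, mapped back to their source reference."""
    return run_mapped_simulation(seed=202, d_max=0.04)


@pytest.fixture(scope="session")
def undamaged_sim():
    """Same experiment with no deamination: only sequencing error remains."""
    return run_mapped_simulation(seed=303, d_max=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
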