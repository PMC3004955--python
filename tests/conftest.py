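"""Shared fixtures: small phantoms, coil sets and protocols.

Session scope keeps the simulation fixtures cheap to reuse; every fixture is
seeded, so the suite is fully deterministic.
"""

import numpy as np
import pytest

from muxepi import forward, phantom, timing


@pytest.fixture(scope="session")
def brain4():
    """4-slice 64^2 phantom with widely spaced slices (multiband-friendly)."""
    return phantom.make_brain_phantom(4, 64, seed=1, slice_thickness_mm=24.0)


@pytest.fixture(scope="session")
def coils16(brain4):
    return phantom.make_coil_sensitivities(brain4, 16, seed=2)


@pytest.fixture(scope="session")
def brain2():
    return phantom.make_brain_phantom(2, 64, seed=1, slice_thickness_mm=24.0)


@pytest.fixture(scope="session")
def coils8_2(brain2):
    return phantom.make_coil_sensitivities(brain2, 8, seed=2)


@pytest.fixture(scope="session")
def rsn_phantom():
    """Small grid for the resting-state pipeline."""
    return phantom.make_brain_phantom(6, 16, seed=3)


def spec_1x1(**kw):
    base = dict(m=1, n=1, r_pe=1, pf=1.0, matrix=64, n_slices=4, tr=2.5, flip_deg=90)
    base.update(kw)
    return timing.ProtocolSpec(**base)


@pytest.fixture(scope="session")
def singleband_calib(brain4, coils16):
    """Fully sampled noiseless single-band k-spaces (modulation off)."""
    return forward.simulate_singleband(
        brain4, coils16, spec_1x1(), off_resonance=False, t2star_decay=False, fat=False
    )


def rel_err(a, b):
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)) / np.linalg.norm(b))
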