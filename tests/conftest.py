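"""Shared fixtures: small deterministic problems reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from smsmap.phantom import make_coil_maps, make_vial_phantom, simulate_acquisition
from smsmap.recon import ReconParams, reconstruct_llrs
from smsmap.sampling import make_super_caipirinha
from smsmap.sequence import build_default_schedule


@pytest.fixture(scope="session")
def schedule60():
    return build_default_schedule(60.0)


@pytest.fixture(scope="session")
def standard_problem(schedule60):
    """Small multiband problem: 48x48, MB=3, R_in=4, 6 coils, noise 0.005."""
    nx = ny = 48
    mb, n_coils = 3, 6
    phantom = make_vial_phantom(nx, ny, mb)
    pattern = make_super_caipirinha(ny, mb, 4, schedule60.n_imaging, center_lines=12)
    coils = make_coil_maps(nx, ny, mb, n_coils, seed=7)
    sim = simulate_acquisition(
        phantom, schedule60, pattern, coils, noise_sd=0.005, seed=7
    )
    return {
        "phantom": phantom,
        "pattern": pattern,
        "coils": coils,
        "sim": sim,
        "schedule": schedule60,
    }


@pytest.fixture(scope="session")
def standard_llrs_run(standard_problem):
    """Full-length (100-iteration) LLRS solve of the standard problem."""
    recon, state = reconstruct_llrs(
        standard_problem["sim"].kspace,
        standard_problem["coils"],
        ReconParams(seed=7),
    )
    return recon, state


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
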