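"""Shared fixtures: canonical nitroxide-at-9.4-T parameter sets."""

import numpy as np
import pytest

from dnpliq import RotationalDiffusion, SpinSystemParams, build_sle_operators
from dnpliq.constants import TWO_PI

#: g-anisotropy angular frequencies of the nitroxide-labeled lipid at 9.4 T
GAMMA02 = -TWO_PI * 373e6
GAMMA22 = TWO_PI * 107e6


@pytest.fixture(scope="session")
def epr_spin():
    """Low-power cw-EPR conditions: B1 = 0.02 G, T1e = 100 ns, T2e = 20 ns."""
    return SpinSystemParams(B0=9.403, B1=0.02, T1e=100e-9, T2e=20e-9)


@pytest.fixture(scope="session")
def dnp_spin():
    """High-power DNP conditions: B1 = 5.5 G, T1e = 100 ns, T2e = 20 ns."""
    return SpinSystemParams(B0=9.403, B1=5.5, T1e=100e-9, T2e=20e-9)


@pytest.fixture(scope="session")
def make_ops():
    """Factory for operator sets at the canonical anisotropies."""

    def _make(spin, tau_rot=5.2e-9, Lmax=10, gamma02=GAMMA02, gamma22=GAMMA22):
        return build_sle_operators(
            Lmax, spin, RotationalDiffusion.from_tau(tau_rot), gamma02, gamma22
        )

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
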