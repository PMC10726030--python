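"""From fitted OE/SE amplitudes to molecular quantities.

The chain: nuclear relaxation times give the leakage factor ``f``; the
fitted Overhauser amplitude gives the coupling factor ``c``; the fitted
solid-effect amplitude gives ``<delta^2> * T1I`` and, with the electron
number density, the FFHS contact distance ``b``; combined with the fitted
translational timescale this yields the relative diffusion coefficient
``D = b^2 / tau``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO, GAMMA_RATIO_EH
from .exceptions import InvalidParameterError
from .ffhs import dipolar_constant

__all__ = [
    "NuclearRelaxation",
    "DerivedMolecular",
    "leakage_factor",
    "coupling_factor",
    "delta2_T1I",
    "contact_distance",
    "diffusion_constant",
    "number_density",
    "derive_molecular_params",
]


@dataclass(frozen=True)
class NuclearRelaxation:
    """Nuclear T1 with (``T1I``) and without (``T1I0``) the radical, in s."""

    T1I: float
    T1I0: float

    def __post_init__(self) -> None:
        if self.T1I <= 0.0 or self.T1I0 <= 0.0:
            raise InvalidParameterError("nuclear T1 values must be positive")
        if self.T1I > self.T1I0:
            raise InvalidParameterError("T1I must not exceed T1I0")

    @property
    def f(self) -> float:
        return leakage_factor(self.T1I, self.T1I0)


def leakage_factor(T1I: float, T1I0: float) -> float:
    """Leakage factor ``f = 1 - T1I/T1I0``."""
    if T1I <= 0.0 or T1I0 <= 0.0:
        raise InvalidParameterError("nuclear T1 values must be positive")
    if T1I > T1I0:
        raise InvalidParameterError("T1I must not exceed T1I0")
    return 1.0 - T1I / T1I0


def coupling_factor(sigma_OE: float, f: float,
                    gamma_ratio: float = GAMMA_RATIO_EH) -> float:
    """Overhauser coupling factor ``c = (sigma_OE / f) * gamma_I/|gamma_S|``
    (dimensionless; multiply by 1000 for per-mille)."""
    if f <= 0.0:
        raise InvalidParameterError("leakage factor must be positive")
    if gamma_ratio <= 0.0:
        raise InvalidParameterError("gamma_ratio must be positive")
    return sigma_OE / f / gamma_ratio


def delta2_T1I(sigma_SE: float, gamma_ratio: float = GAMMA_RATIO_EH) -> float:
    """``<delta^2> * T1I = sigma_SE * gamma_I/|gamma_S|`` in 1/s."""
    if sigma_SE < 0.0:
        raise InvalidParameterError("sigma_SE must be >= 0")
    if gamma_ratio <= 0.0:
        raise InvalidParameterError("gamma_ratio must be positive")
    return sigma_SE / gamma_ratio


def contact_distance(sigma_SE: float, T1I: float, N: float,
                     gamma_ratio: float = GAMMA_RATIO_EH,
                     D_dip: float | None = None) -> float:
    """FFHS contact distance ``b`` (nm) implied by the fitted SE amplitude.

    Inverts ``<delta^2> = Ddip^2 (6 pi / 5) N / (3 b^3)`` with
    ``<delta^2> = (sigma_SE * gamma_I/|gamma_S|) / T1I``.
    """
    if T1I <= 0.0 or N <= 0.0 or sigma_SE <= 0.0:
        raise InvalidParameterError("sigma_SE, T1I and N must be positive")
    if D_dip is None:
        D_dip = dipolar_constant()
    d2 = delta2_T1I(sigma_SE, gamma_ratio) / T1I
    return (D_dip ** 2 * (6.0 * np.pi / 5.0) * N / (3.0 * d2)) ** (1.0 / 3.0)


def diffusion_constant(b: float, tau_ffhs: float) -> float:
    """Relative translational diffusion coefficient ``b^2/tau`` in nm^2/us
    for ``b`` in nm and ``tau_ffhs`` in s."""
    if b <= 0.0 or tau_ffhs <= 0.0:
        raise InvalidParameterError("b and tau_ffhs must be positive")
    return b ** 2 / (tau_ffhs * 1e6)


def number_density(molar_ratio: float, molecular_volume: float
                   ) -> tuple[float, float]:
    """Electron number density from a labeling ratio and host molecular
    volume (nm^3).

    Returns ``(N, concentration)`` with ``N`` in nm^-3 and the molar
    concentration in mM.
    """
    if molar_ratio <= 0.0 or molecular_volume <= 0.0:
        raise InvalidParameterError("ratio and volume must be positive")
    N = 1.0 / (molar_ratio * molecular_volume)
    conc_mM = N * 1e27 / AVOGADRO  # mol/m^3 == mmol/L
    return N, conc_mM


@dataclass(frozen=True)
class DerivedMolecular:
    """One row of the derived-parameter table."""

    f: float
    c: float
    delta2_T1I: float
    b: float
    D_ffhs: float
    N: float
    gamma_ratio: float


def derive_molecular_params(sigma_OE: float, sigma_SE: float, T1I: float,
                            T1I0: float, tau_ffhs: float, N: float,
                            gamma_ratio: float = GAMMA_RATIO_EH
                            ) -> DerivedMolecular:
    """Run the full amplitude-to-molecular-parameter chain for one sample."""
    f = leakage_factor(T1I, T1I0)
    c = coupling_factor(sigma_OE, f, gamma_ratio)
    d2t = delta2_T1I(sigma_SE, gamma_ratio)
    b = contact_distance(sigma_SE, T1I, N, gamma_ratio)
    D = diffusion_constant(b, tau_ffhs)
    return DerivedMolecular(f=f, c=c, delta2_T1I=d2t, b=b, D_ffhs=D, N=N,
                            gamma_ratio=gamma_ratio)
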