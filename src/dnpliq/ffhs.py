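"""Force-free hard-sphere (FFHS) translational spectral density.

The FFHS model describes the modulation of the electron--nucleus dipolar
interaction by the relative translational diffusion of two hard spheres
with contact distance ``b`` and relative diffusion coefficient ``D``.  Its
reduced spectral density ``j11`` (units of time) depends on the single
timescale ``tau = b^2 / D``; the overall scale of the dipolar interaction
is carried by ``<delta^2> = Ddip^2 * (6 pi / 5) * N / (3 b^3)``, where ``N``
is the number density of electronic spins.

This module also provides the evaluation of a scalar spectral density at a
(complex, non-Hermitian) matrix argument via eigendecomposition, which is
how the static-coupling rate expressions are carried over to liquids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .constants import GAMMA_E, GAMMA_H, HBAR, MU0_OVER_4PI
from .exceptions import (
    InvalidParameterError,
    NumericalDegeneracyError,
    UnstableDynamicsError,
)

__all__ = [
    "FfhsParams",
    "dipolar_constant",
    "j11_ffhs",
    "ffhs_j11",
    "avg_delta2",
    "matrix_spectral_density",
]

#: relative tolerance for "decaying mode" checks Re(s) >= -tol*|s|
_STABILITY_RTOL = 1e-6


def dipolar_constant(gamma_S: float = GAMMA_E, gamma_I: float = GAMMA_H) -> float:
    """Dipolar constant ``(mu0/4pi) * hbar * |gamma_S| * |gamma_I|``.

    Returned in rad/s * nm^3.  For an electron--proton pair this is about
    2*pi * 79 kHz nm^3.
    """
    if gamma_S == 0.0 or not np.isfinite(gamma_S) or not np.isfinite(gamma_I):
        raise InvalidParameterError("gyromagnetic ratios must be finite and gamma_S nonzero")
    return MU0_OVER_4PI * HBAR * abs(gamma_S) * abs(gamma_I) * 1e27


def j11_ffhs(s, tau: float):
    """Reduced FFHS spectral density (units of time) at Laplace argument ``s``.

    ``j11(s) = tau * (x + 4) / (x^3 + 4 x^2 + 9 x + 9)`` with
    ``x = sqrt(s * tau)`` on the principal branch.  Defined for
    ``Re(s) >= 0`` (decaying modes); ``j11(0) = 4 tau / 9``.
    """
    if tau <= 0.0 or not np.isfinite(tau):
        raise InvalidParameterError("tau must be positive and finite")
    sv = np.asarray(s, dtype=complex)
    scale = np.maximum(np.abs(sv), 1.0 / tau)
    if np.any(sv.real < -_STABILITY_RTOL * scale):
        raise InvalidParameterError("j11 requires Re(s) >= 0 (decaying modes)")
    x = np.sqrt(sv * tau)
    out = tau * (x + 4.0) / (x ** 3 + 4.0 * x ** 2 + 9.0 * x + 9.0)
    if np.isscalar(s) or np.ndim(s) == 0:
        return complex(out)
    return out


def ffhs_j11(tau: float) -> Callable:
    """Return the reduced FFHS spectral density as a one-argument callable."""
    if tau <= 0.0 or not np.isfinite(tau):
        raise InvalidParameterError("tau must be positive and finite")

    def j11(s):
        return j11_ffhs(s, tau)

    j11.tau = tau
    return j11


def avg_delta2(b: float, N: float, D_dip: float | None = None) -> float:
    """Sample-averaged squared dipolar coupling ``<delta^2>`` ((rad/s)^2).

    ``<delta^2> = Ddip^2 * (6 pi / 5) * N / (3 b^3)`` with the contact
    distance ``b`` in nm, the electron number density ``N`` in nm^-3 and the
    dipolar constant in rad/s nm^3 (electron--proton by default).
    """
    if b <= 0.0 or N < 0.0:
        raise InvalidParameterError("need b > 0 and N >= 0")
    if D_dip is None:
        D_dip = dipolar_constant()
    return D_dip ** 2 * (6.0 * np.pi / 5.0) * N / (3.0 * b ** 3)


@dataclass(frozen=True)
class FfhsParams:
    """FFHS model parameters.

    ``b`` contact distance (nm); ``D_trans`` relative translational
    diffusion coefficient (nm^2/us); ``N`` electron number density (nm^-3),
    optional and needed only for the absolute dipolar scale.
    """

    b: float
    D_trans: float
    N: float | None = None

    def __post_init__(self) -> None:
        if self.b <= 0.0 or self.D_trans <= 0.0:
            raise InvalidParameterError("need b > 0 and D_trans > 0")
        if self.N is not None and self.N < 0.0:
            raise InvalidParameterError("N must be >= 0")

    @property
    def tau(self) -> float:
        """Diffusive timescale ``b^2 / D`` in seconds."""
        return self.b ** 2 / self.D_trans * 1e-6

    @property
    def avg_delta2(self) -> float:
        if self.N is None:
            raise InvalidParameterError("N is required for avg_delta2")
        return avg_delta2(self.b, self.N)

    def j11(self) -> Callable:
        return ffhs_j11(self.tau)


def matrix_spectral_density(j11: Callable, B: np.ndarray,
                            cond_max: float = 1e8) -> np.ndarray:
    """Evaluate a scalar spectral density at a square-matrix argument.

    Solves the eigenvalue problem ``B U = U diag(lambda)`` and returns
    ``Q = U diag(j11(lambda)) U^-1``.  Supports stacked input of shape
    ``(..., n, n)``.  Raises :class:`NumericalDegeneracyError` when the
    eigenvector matrix is ill-conditioned (near-defective ``B``) and
    :class:`UnstableDynamicsError` when an eigenvalue has a large negative
    real part (growing mode: not a relaxation matrix).
    """
    B = np.asarray(B, dtype=complex)
    if B.ndim < 2 or B.shape[-1] != B.shape[-2]:
        raise InvalidParameterError("B must be a (stack of) square matrix")
    lam, U = np.linalg.eig(B)
    scale = np.maximum(np.abs(lam).max(axis=-1, keepdims=True), 1e-300)
    if np.any(lam.real < -_STABILITY_RTOL * scale):
        raise UnstableDynamicsError(
            "matrix argument has an eigenvalue with a large negative real part"
        )
    cond = np.linalg.cond(U)
    if np.any(cond > cond_max):
        raise NumericalDegeneracyError(
            f"eigenvector condition number exceeds {cond_max:g}"
        )
    # clip tiny negative real parts so the principal branch stays valid
    lam_safe = np.where(lam.real < 0.0, 1j * lam.imag, lam)
    ell = j11(lam_safe)
    Q = (U * ell[..., None, :]) @ np.linalg.inv(U)
    return Q
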