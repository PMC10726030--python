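"""Homogeneous-line (Lorentzian) reference physics.

Steady state of the classical Bloch equations in the rotating frame, the
saturation factor, and the solid-effect rate constants ``v+`` and ``p v-``
for a single Lorentzian EPR line — both for a static (``solid``)
electron--nucleus dipolar coupling and for a coupling modulated by
translational diffusion (``liquid``), where the inverse Bloch matrix is
replaced by a spectral-density function of the matrix.

All offsets and frequencies are angular (rad/s).  Magnetizations and
coherences are expressed relative to the equilibrium electronic
magnetization, which is therefore never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Callable

import numpy as np

from .constants import GAMMA_H, GAMMA_RATIO_EH, HBAR, MU_B
from .exceptions import InvalidParameterError

__all__ = [
    "SpinSystemParams",
    "SteadyStateSolution",
    "SolidDipolarParams",
    "RatePoint",
    "EnhancementResult",
    "bloch_matrix",
    "bloch_steady_state",
    "se_rates_solid_lorentzian",
    "se_rates_liquid_lorentzian",
    "enhancement_from_rates",
]


@dataclass(frozen=True)
class SpinSystemParams:
    """Electronic spin system and microwave drive in the rotating frame.

    Parameters
    ----------
    B0 : float
        Static magnetic field (T).
    B1 : float
        Microwave field amplitude in the rotating frame (G).
    T1e, T2e : float
        Electronic spin-lattice and spin-spin relaxation times (s).
    omega_I : float, optional
        Nuclear Larmor angular frequency (rad/s).  Defaults to protons at
        ``B0``.
    g0 : float, optional
        Isotropic electronic g value used to convert ``B1`` to the Rabi
        frequency ``omega1``.
    """

    B0: float
    B1: float
    T1e: float
    T2e: float
    omega_I: float | None = None
    g0: float = 2.0023

    def __post_init__(self) -> None:
        if self.omega_I is None:
            object.__setattr__(self, "omega_I", GAMMA_H * self.B0)
        vals = (self.B0, self.B1, self.T1e, self.T2e, self.omega_I, self.g0)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError("spin parameters must be finite")
        if self.T1e <= 0.0 or self.T2e <= 0.0:
            raise InvalidParameterError("T1e and T2e must be positive")
        if self.B0 <= 0.0 or self.B1 < 0.0:
            raise InvalidParameterError("need B0 > 0 and B1 >= 0")

    @property
    def omega1(self) -> float:
        """Rabi angular frequency g0*muB*B1/hbar (rad/s); B1 is in G."""
        return self.g0 * MU_B / HBAR * self.B1 * 1e-4

    @property
    def omega0(self) -> float:
        """Isotropic electronic Larmor angular frequency (rad/s)."""
        return self.g0 * MU_B * self.B0 / HBAR

    @property
    def R1(self) -> float:
        return 1.0 / self.T1e

    @property
    def R2(self) -> float:
        return 1.0 / self.T2e

    def replace(self, **kwargs) -> "SpinSystemParams":
        return _dc_replace(self, **kwargs)


@dataclass(frozen=True)
class SteadyStateSolution:
    """Steady-state electronic magnetization relative to its thermal value.

    ``abs`` and ``dsp`` are the in-phase (absorptive) and out-of-phase
    (dispersive) cw-EPR components; ``s`` is the saturation factor
    ``1 - sz/szeq`` and equals ``-omega1*T1e*abs`` identically.
    """

    sx: np.ndarray
    sy: np.ndarray
    sz: np.ndarray
    abs: np.ndarray
    dsp: np.ndarray
    s: np.ndarray


@dataclass(frozen=True)
class SolidDipolarParams:
    """Squared dipolar coupling strength delta^2 ((rad/s)^2) of one fixed
    electron--nucleus configuration."""

    delta2: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta2) or self.delta2 < 0.0:
            raise InvalidParameterError("delta2 must be finite and >= 0")


@dataclass(frozen=True)
class RatePoint:
    """Offset-resolved solid-effect rate constants (1/s)."""

    v_plus: np.ndarray
    pv_minus: np.ndarray
    R1IA: np.ndarray


@dataclass(frozen=True)
class EnhancementResult:
    """Solid-effect enhancement: exact form, multiplicative approximation,
    and the product ``v+ * T1I`` that controls the approximation error."""

    exact: np.ndarray
    multiplicative: np.ndarray
    v_plus_T1I: np.ndarray


def _check_offsets(offset) -> np.ndarray:
    offs = np.atleast_1d(np.asarray(offset, dtype=float))
    if not np.all(np.isfinite(offs)):
        raise InvalidParameterError("offsets must be finite")
    return offs


def bloch_matrix(offset: float, spin: SpinSystemParams, omega_i: float = 0.0,
                 omega1: float | None = None) -> np.ndarray:
    """The 3x3 (complex) Bloch relaxation matrix, optionally with ``i*omega_i``
    added to the diagonal as needed for the electron--nucleus coherences."""
    w1 = spin.omega1 if omega1 is None else omega1
    z = 1j * omega_i
    return np.array(
        [
            [spin.R2 + z, offset, 0.0],
            [-offset, spin.R2 + z, w1],
            [0.0, -w1, spin.R1 + z],
        ],
        dtype=complex,
    )


def _bloch_stack(offsets: np.ndarray, spin: SpinSystemParams, omega_i: float,
                 omega1: float | None = None) -> np.ndarray:
    w1 = spin.omega1 if omega1 is None else omega1
    n = offsets.shape[0]
    B = np.zeros((n, 3, 3), dtype=complex)
    z = 1j * omega_i
    B[:, 0, 0] = spin.R2 + z
    B[:, 1, 1] = spin.R2 + z
    B[:, 2, 2] = spin.R1 + z
    B[:, 0, 1] = offsets
    B[:, 1, 0] = -offsets
    B[:, 1, 2] = w1
    B[:, 2, 1] = -w1
    return B


def bloch_steady_state(offset, spin: SpinSystemParams) -> SteadyStateSolution:
    """Closed-form steady state of the Bloch equations at the given offset(s).

    ``abs = -omega1 / P0`` with ``P0 = R2 + omega1^2*T1 + offset^2*T2``;
    ``dsp = -offset*T2*abs`` and ``s = -omega1*T1*abs``.
    """
    offs = _check_offsets(offset)
    w1, T1, T2 = spin.omega1, spin.T1e, spin.T2e
    p0 = spin.R2 + w1 ** 2 * T1 + offs ** 2 * T2
    absorption = -w1 / p0
    dispersion = -offs * T2 * absorption
    sat = -w1 * T1 * absorption
    return SteadyStateSolution(
        sx=dispersion, sy=absorption, sz=1.0 - sat,
        abs=absorption, dsp=dispersion, s=sat,
    )


def se_rates_solid_lorentzian(offset, dip, spin: SpinSystemParams,
                              method: str = "closed_form") -> RatePoint:
    """Solid-effect rate constants for a static dipolar coupling and a
    homogeneous EPR line.

    ``method='closed_form'`` evaluates the explicit expressions in which the
    combinations ``P`` and ``P0`` appear; ``method='matrix'`` obtains the
    same rates by numerically inverting the 3x3 coherence matrix ``B``
    (the Bloch matrix with ``i*omega_I`` on the diagonal).  The two routes
    agree to machine precision and serve as mutual cross-checks.
    """
    offs = _check_offsets(offset)
    delta2 = dip.delta2 if isinstance(dip, SolidDipolarParams) else float(dip)
    if delta2 < 0.0:
        raise InvalidParameterError("delta2 must be >= 0")
    wi = spin.omega_I
    if wi is None or wi <= 0.0:
        raise InvalidParameterError("omega_I must be positive for SE rates")
    w1 = spin.omega1
    r1c = spin.R1 + 1j * wi
    r2c = spin.R2 + 1j * wi
    R1IA = delta2 * np.real(1.0 / r1c)

    if method == "closed_form":
        P = r2c + w1 ** 2 / r1c + offs ** 2 / r2c
        p0 = spin.R2 + w1 ** 2 * spin.T1e + offs ** 2 * spin.T2e
        v_plus = -delta2 * w1 ** 2 * np.real(1.0 / (r1c ** 2 * P))
        pv_minus = -delta2 * w1 ** 2 * offs / p0 * np.imag(
            (1.0 / spin.R2 + 1.0 / r2c) / (r1c * P)
        )
    elif method == "matrix":
        B = _bloch_stack(offs, spin, wi)
        Binv = np.linalg.inv(B)
        p0 = spin.R2 + w1 ** 2 * spin.T1e + offs ** 2 * spin.T2e
        v_plus = delta2 * np.real(Binv[:, 2, 2]) - R1IA
        pv_minus = -delta2 * w1 / p0 * np.imag(
            Binv[:, 2, 0] + offs * spin.T2e * Binv[:, 2, 1]
        )
    else:  # pragma: no cover - defensive
        raise ValueError(f"unknown method {method!r}")

    return RatePoint(
        v_plus=v_plus,
        pv_minus=pv_minus,
        R1IA=np.broadcast_to(R1IA, offs.shape).copy(),
    )


def se_rates_liquid_lorentzian(offset, avg_delta2: float,
                               j11: Callable[[np.ndarray], np.ndarray],
                               spin: SpinSystemParams) -> RatePoint:
    """Solid-effect rate constants for a dipolar coupling modulated by
    molecular motion with reduced spectral density ``j11``.

    The inverse coherence matrix of the static case is replaced by
    ``Q = j11(B)``, evaluated through the eigendecomposition of ``B``; the
    thermal contribution reduces to the scalar form
    ``R1IA = <delta^2> * Re{j11(R1 + i*omega_I)}``.
    """
    from .ffhs import matrix_spectral_density  # local import, no cycle at load

    offs = _check_offsets(offset)
    wi = spin.omega_I
    if wi is None or wi <= 0.0:
        raise InvalidParameterError("omega_I must be positive for SE rates")
    w1 = spin.omega1
    r1c = spin.R1 + 1j * wi
    B = _bloch_stack(offs, spin, wi)
    Q = matrix_spectral_density(j11, B)
    R1IA = avg_delta2 * float(np.real(j11(np.asarray(r1c))))
    p0 = spin.R2 + w1 ** 2 * spin.T1e + offs ** 2 * spin.T2e
    v_plus = avg_delta2 * np.real(Q[:, 2, 2]) - R1IA
    pv_minus = -avg_delta2 * w1 / p0 * np.imag(
        Q[:, 2, 0] + offs * spin.T2e * Q[:, 2, 1]
    )
    return RatePoint(
        v_plus=v_plus,
        pv_minus=pv_minus,
        R1IA=np.broadcast_to(R1IA, offs.shape).copy(),
    )


def enhancement_from_rates(pv_minus, v_plus, T1I: float,
                           gamma_ratio: float = GAMMA_RATIO_EH
                           ) -> EnhancementResult:
    """Solid-effect enhancement from the rate constants.

    Returns both the exact form
    ``eps = p*v- * T1I / (1 + v+*T1I) * |gamma_S|/gamma_I``
    and its multiplicative approximation (valid for ``v+*T1I << 1``), along
    with the product ``v+*T1I`` so callers can judge the approximation.
    """
    if T1I <= 0.0 or not np.isfinite(T1I):
        raise InvalidParameterError("T1I must be positive and finite")
    if gamma_ratio <= 0.0:
        raise InvalidParameterError("gamma_ratio must be positive")
    pvm = np.asarray(pv_minus, dtype=float)
    vp = np.asarray(v_plus, dtype=float)
    vpt = vp * T1I
    multiplicative = pvm * T1I * gamma_ratio
    exact = multiplicative / (1.0 + vpt)
    return EnhancementResult(exact=exact, multiplicative=multiplicative,
                             v_plus_T1I=vpt)
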