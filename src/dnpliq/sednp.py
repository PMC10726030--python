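"""Solid-effect rate profiles under slow tumbling, and the mixed OE+SE
DNP spectrum model.

Two dynamical regimes are covered with the same operator set:

* ``solid`` — the electron--nucleus dipolar coupling is static on all spin
  timescales (quotation-mark solids: tumbling of the radical still runs);
  the rates follow from the inverse of the expanded coherence matrix ``B``.
* ``liquid`` — the coupling is modulated by translational diffusion; the
  inverse of ``B`` is replaced by ``Q = j11(B)`` with the reduced spectral
  density of the motional model (FFHS here), evaluated by
  eigendecomposition.

The mixed DNP spectrum is assembled as
``eps(D) = -sigma_OE * s(D - shift) + sigma_SE * (pv-/<delta^2>)(D - shift)``
so that the Overhauser feature near zero offset is negative (dipolar OE)
and the solid-effect peak near ``+omega_I`` is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import InvalidParameterError, NumericalDegeneracyError
from .ffhs import matrix_spectral_density
from .sle import SleOperatorSet, _e1

__all__ = [
    "RateProfile",
    "EnhancementModelParams",
    "DnpSpectrum",
    "se_rates_slow_solid",
    "se_rates_slow_liquid",
    "dnp_spectrum_model",
]


@dataclass(frozen=True)
class RateProfile:
    """Offset-resolved solid-effect rates and electronic saturation.

    ``v_plus`` and ``pv_minus`` in 1/s (scaled by delta^2 or <delta^2>),
    ``R1IA`` the coherence contribution to thermal nuclear relaxation,
    ``s`` the saturation factor and ``p = 1 - s`` the non-saturation.
    """

    offsets: np.ndarray
    v_plus: np.ndarray
    pv_minus: np.ndarray
    R1IA: np.ndarray
    s: np.ndarray

    @property
    def p(self) -> np.ndarray:
        return 1.0 - self.s

    @property
    def v_minus(self) -> np.ndarray:
        return self.pv_minus / self.p


@dataclass(frozen=True)
class EnhancementModelParams:
    """Scaling parameters of the mixed OE+SE enhancement model.

    ``sigma_OE`` is dimensionless, ``sigma_SE`` has units of 1/s (it
    multiplies the timescale ``pv-/<delta^2>``), ``shift`` is a horizontal
    offset correction in rad/s.  ``sigma_OE`` is stored as the positive
    magnitude; the dipolar (negative) sign of the OE contribution is applied
    inside the model.
    """

    sigma_OE: float
    sigma_SE: float
    shift: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.sigma_OE, self.sigma_SE, self.shift)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError("model parameters must be finite")


@dataclass(frozen=True)
class DnpSpectrum:
    """Mixed DNP enhancement profile and its OE / SE components."""

    offsets: np.ndarray
    epsilon: np.ndarray
    oe: np.ndarray
    se: np.ndarray


def _check_se_inputs(ops: SleOperatorSet, offsets) -> np.ndarray:
    offs = np.atleast_1d(np.asarray(offsets, dtype=float))
    if not np.all(np.isfinite(offs)):
        raise InvalidParameterError("offsets must be finite")
    if ops.spin.omega_I is None or ops.spin.omega_I <= 0.0:
        raise InvalidParameterError("omega_I must be positive for SE rates")
    return offs


def _saturation(ops: SleOperatorSet, offs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (z, s): z = P0^-1 |00> and the saturation factor."""
    spin = ops.spin
    P0 = ops.p0_stack(offs)
    z = np.linalg.solve(P0, _e1(offs.size, ops.ntot)[..., None])[..., 0]
    s = spin.omega1 ** 2 * spin.T1e * z[:, 0]
    return z, s


def _mixed_stack(ops: SleOperatorSet, offs: np.ndarray) -> np.ndarray:
    """``R2^-1 Delta + Delta (R2 + i wI)^-1`` stacked over offsets."""
    dm = ops.delta_stack(offs)
    inv2 = 1.0 / ops.r2_diag
    inv2c = 1.0 / (ops.r2_diag + 1j * ops.spin.omega_I)
    return inv2[None, :, None] * dm + dm * inv2c[None, None, :]


def se_rates_slow_solid(offsets, ops: SleOperatorSet, delta2: float,
                        method: str = "reduced") -> RateProfile:
    """Solid-effect rates for a static dipolar coupling under slow tumbling.

    ``method='reduced'`` uses the ``ntot x ntot`` matrices ``P`` and ``P0``;
    ``method='full'`` inverts the ``3*ntot`` coherence matrix ``B`` (the
    route that generalizes directly to liquids) as a cross-check.
    """
    offs = _check_se_inputs(ops, offsets)
    if delta2 < 0.0:
        raise InvalidParameterError("delta2 must be >= 0")
    spin = ops.spin
    w1 = spin.omega1
    wi = spin.omega_I
    r1c = spin.R1 + 1j * wi  # L = 0 element of R1 + i*omega_I
    n = ops.ntot
    z, s = _saturation(ops, offs)
    R1IA = delta2 * np.real(1.0 / r1c)

    if method == "reduced":
        P = ops.p_stack(offs)
        e1c = _e1(offs.size, n, dtype=complex)
        a = np.linalg.solve(P, e1c[..., None])[..., 0]  # first column of P^-1
        v_plus = -delta2 * w1 ** 2 * np.real(a[:, 0] / r1c ** 2)
        bt = np.linalg.solve(np.swapaxes(P, 1, 2), e1c[..., None])[..., 0]  # first row of P^-1
        Mz = np.einsum("mij,mj->mi", _mixed_stack(ops, offs), z + 0j)
        core = np.einsum("mi,mi->m", bt, Mz)
        pv_minus = -delta2 * w1 ** 2 * np.imag(core / r1c)
    elif method == "full":
        B = ops.bigb_stack(offs, wi)
        Binv = np.linalg.inv(B)
        v_plus = delta2 * np.real(Binv[:, 2 * n, 2 * n]) - R1IA
        dm = ops.delta_stack(offs)
        r2invdm = (1.0 / ops.r2_diag)[None, :, None] * dm
        row = Binv[:, 2 * n, 0:n] + np.einsum(
            "mj,mjk->mk", Binv[:, 2 * n, n:2 * n], r2invdm
        )
        pv_minus = -delta2 * w1 * np.imag(np.einsum("mk,mk->m", row, z + 0j))
    else:  # pragma: no cover - defensive
        raise ValueError(f"unknown method {method!r}")

    return RateProfile(
        offsets=offs, v_plus=v_plus, pv_minus=pv_minus,
        R1IA=np.broadcast_to(R1IA, offs.shape).copy(), s=s,
    )


def _q_of_big_b(ops: SleOperatorSet, offs: np.ndarray, j11: Callable) -> np.ndarray:
    """``Q = j11(B)`` per offset with the degeneracy-retry policy: an
    ill-conditioned eigendecomposition is retried once at a 1e-8-relative
    randomly perturbed offset before erroring."""
    wi = ops.spin.omega_I
    B = ops.bigb_stack(offs, wi)
    try:
        return matrix_spectral_density(j11, B)
    except NumericalDegeneracyError:
        pass
    rng = np.random.default_rng(0)
    Q = np.empty_like(B)
    for k in range(offs.size):
        try:
            Q[k] = matrix_spectral_density(j11, B[k])
        except NumericalDegeneracyError:
            scale = offs[k] if offs[k] != 0.0 else wi
            pert = offs[k] + 1e-8 * scale * (rng.random() - 0.5)
            Bk = ops.bigb_stack(np.array([pert]), wi)[0]
            Q[k] = matrix_spectral_density(j11, Bk)
    return Q


def se_rates_slow_liquid(offsets, ops: SleOperatorSet, avg_delta2: float,
                         j11: Callable) -> RateProfile:
    """Solid-effect rates for an FFHS-modulated (or any ``j11``) dipolar
    coupling under slow tumbling.

    With ``avg_delta2 = 1`` the returned ``pv_minus`` equals the timescale
    profile ``pv-/<delta^2>`` directly (the rates scale linearly).
    ``R1IA`` uses the scalar identity
    ``<delta^2> * Re{j11(R1 + i*omega_I)}``, which is unaffected by the g
    anisotropy.
    """
    offs = _check_se_inputs(ops, offsets)
    if avg_delta2 < 0.0:
        raise InvalidParameterError("avg_delta2 must be >= 0")
    spin = ops.spin
    w1 = spin.omega1
    wi = spin.omega_I
    r1c = spin.R1 + 1j * wi
    n = ops.ntot
    z, s = _saturation(ops, offs)
    Q = _q_of_big_b(ops, offs, j11)
    R1IA = avg_delta2 * float(np.real(j11(np.asarray(r1c))))
    v_plus = avg_delta2 * np.real(Q[:, 2 * n, 2 * n]) - R1IA
    dm = ops.delta_stack(offs)
    r2invdm = (1.0 / ops.r2_diag)[None, :, None] * dm
    row = Q[:, 2 * n, 0:n] + np.einsum(
        "mj,mjk->mk", Q[:, 2 * n, n:2 * n], r2invdm
    )
    pv_minus = -avg_delta2 * w1 * np.imag(np.einsum("mk,mk->m", row, z + 0j))
    return RateProfile(
        offsets=offs, v_plus=v_plus, pv_minus=pv_minus,
        R1IA=np.broadcast_to(R1IA, offs.shape).copy(), s=s,
    )


def dnp_spectrum_model(offsets, ops: SleOperatorSet,
                       params: EnhancementModelParams,
                       j11: Callable) -> DnpSpectrum:
    """Mixed OE+SE DNP enhancement profile.

    ``eps(D) = -sigma_OE * s(D - shift)
    + sigma_SE * (pv-/<delta^2>)(D - shift)``.
    The saturation profile carries the (power-broadened) OE line shape; the
    SE part uses the liquid-state rates computed at unit dipolar scale so
    that ``sigma_SE`` carries all amplitude information.
    """
    offs = np.atleast_1d(np.asarray(offsets, dtype=float))
    shifted = offs - params.shift
    rates = se_rates_slow_liquid(shifted, ops, 1.0, j11)
    oe = -params.sigma_OE * rates.s
    se = params.sigma_SE * rates.pv_minus
    return DnpSpectrum(offsets=offs, epsilon=oe + se, oe=oe, se=se)
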