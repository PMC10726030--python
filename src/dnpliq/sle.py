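"""Slow-tumbling cw-EPR machinery for an anisotropic g tensor.

The orientational probability density of an isotropically tumbling radical
is expanded in Wigner rotation functions.  Keeping only the secular part of
the anisotropic electronic Zeeman interaction, the surviving expansion
coefficients carry even ``L <= Lmax`` and even ``0 <= M <= L`` (after
symmetrization over the sign of ``M``), which turns each scalar element of
the Bloch matrix into an ``ntot x ntot`` matrix over the ``(L, M)`` index
space.  Relaxation and tumbling stay diagonal; only the offset block
``Delta*E + gamma02*C0 + gamma22*C2`` mixes different ``(L, M)``, through
coupling matrices built from Clebsch--Gordan coefficients.

The steady state yields the absorptive/dispersive cw-EPR components and the
saturation factor from the inverse of a single ``ntot x ntot`` matrix
``P0``; a dense solve of the full ``3*ntot`` system is kept as a
cross-check route.  Derivative-mode spectra (with optional dispersion
admixture) use the analytic derivative of ``P0`` with respect to the offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .bloch import SpinSystemParams
from .constants import HBAR, MU_B
from .exceptions import InvalidParameterError

__all__ = [
    "GTensor",
    "RotationalDiffusion",
    "SleBasis",
    "SleOperatorSet",
    "EprResult",
    "gamma_anisotropies",
    "gtensor_from_anisotropies",
    "clebsch_gordan",
    "build_basis",
    "build_coupling_matrices",
    "build_sle_operators",
    "epr_slow_tumbling",
    "epr_derivative_spectrum",
]


@dataclass(frozen=True)
class GTensor:
    """Principal g values in the molecular frame."""

    gxx: float
    gyy: float
    gzz: float

    def __post_init__(self) -> None:
        vals = (self.gxx, self.gyy, self.gzz)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError("g values must be finite")
        if any(abs(v - 2.0) > 0.1 for v in vals):
            warnings.warn(
                "g values far from 2: not nitroxide-like", stacklevel=2
            )

    @property
    def g0(self) -> float:
        """Isotropic g value (gxx + gyy + gzz) / 3."""
        return (self.gxx + self.gyy + self.gzz) / 3.0


@dataclass(frozen=True)
class RotationalDiffusion:
    """Isotropic rotational diffusion; ``tau_rot = 1/(6*D_rot)`` is the
    rank-2 tumbling time."""

    D_rot: float

    def __post_init__(self) -> None:
        if self.D_rot <= 0.0 or not np.isfinite(self.D_rot):
            raise InvalidParameterError("D_rot must be positive and finite")

    @property
    def tau_rot(self) -> float:
        return 1.0 / (6.0 * self.D_rot)

    @classmethod
    def from_tau(cls, tau_rot: float) -> "RotationalDiffusion":
        if tau_rot <= 0.0 or not np.isfinite(tau_rot):
            raise InvalidParameterError("tau_rot must be positive and finite")
        return cls(D_rot=1.0 / (6.0 * tau_rot))


def gamma_anisotropies(g: GTensor, B0: float) -> tuple[float, float]:
    """Secular g-anisotropy angular frequencies at static field ``B0``.

    ``gamma02 = (2/3) * [gzz - (gxx + gyy)/2] * muB * B0 / hbar`` and
    ``gamma22 = (gxx - gyy) / sqrt(6) * muB * B0 / hbar``.
    """
    if B0 <= 0.0:
        raise InvalidParameterError("B0 must be positive")
    c = MU_B * B0 / HBAR
    gamma02 = (2.0 / 3.0) * (g.gzz - 0.5 * (g.gxx + g.gyy)) * c
    gamma22 = (g.gxx - g.gyy) / np.sqrt(6.0) * c
    return gamma02, gamma22


def gtensor_from_anisotropies(gamma02: float, gamma22: float, B0: float,
                              gzz: float = 2.0023) -> GTensor:
    """Invert :func:`gamma_anisotropies` with ``gzz`` pinned (the field/shift
    degeneracy leaves one principal value undetermined)."""
    if B0 <= 0.0:
        raise InvalidParameterError("B0 must be positive")
    c = MU_B * B0 / HBAR
    mean_xy = gzz - 1.5 * gamma02 / c
    diff_xy = np.sqrt(6.0) * gamma22 / c
    return GTensor(gxx=mean_xy + 0.5 * diff_xy, gyy=mean_xy - 0.5 * diff_xy,
                   gzz=gzz)


def _as_half_int(x, name: str) -> int:
    two = 2.0 * float(x)
    if not np.isfinite(two) or abs(two - round(two)) > 1e-9:
        raise InvalidParameterError(
            f"{name}={x!r} is not integer or half-integer"
        )
    return int(round(two))


@lru_cache(maxsize=None)
def _cg_cached(tj1: int, tm1: int, tj2: int, tm2: int, tJ: int, tM: int) -> float:
    from sympy import Rational
    from sympy.physics.quantum.cg import CG

    val = CG(
        Rational(tj1, 2), Rational(tm1, 2),
        Rational(tj2, 2), Rational(tm2, 2),
        Rational(tJ, 2), Rational(tM, 2),
    ).doit()
    return float(val)


def clebsch_gordan(j1, m1, j2, m2, J, M) -> float:
    """Clebsch--Gordan coefficient ``<j1 m1 j2 m2 | J M>``.

    Evaluated exactly (rational square roots) and returned as a float;
    zero whenever the triangle or projection selection rules fail.
    """
    args = [_as_half_int(v, n) for v, n in
            zip((j1, m1, j2, m2, J, M), ("j1", "m1", "j2", "m2", "J", "M"))]
    tj1, tm1, tj2, tm2, tJ, tM = args
    if tj1 < 0 or tj2 < 0 or tJ < 0:
        raise InvalidParameterError("angular momenta must be non-negative")
    if abs(tm1) > tj1 or abs(tm2) > tj2 or abs(tM) > tJ:
        return 0.0
    if tm1 + tm2 != tM:
        return 0.0
    if tJ < abs(tj1 - tj2) or tJ > tj1 + tj2:
        return 0.0
    return _cg_cached(tj1, tm1, tj2, tm2, tJ, tM)


@dataclass(frozen=True)
class SleBasis:
    """Ordered ``(L, M)`` index set with even ``L <= Lmax`` and even
    ``0 <= M <= L``; ``ntot = Lmax^2/8 + 3*Lmax/4 + 1``."""

    Lmax: int
    index_list: tuple[tuple[int, int], ...]
    ntot: int


def build_basis(Lmax: int) -> SleBasis:
    """Construct the truncated ``(L, M)`` basis for even ``Lmax >= 0``."""
    if not isinstance(Lmax, (int, np.integer)) or Lmax < 0 or Lmax % 2 != 0:
        raise InvalidParameterError("Lmax must be an even integer >= 0")
    idx = tuple(
        (L, M) for L in range(0, Lmax + 1, 2) for M in range(0, L + 1, 2)
    )
    return SleBasis(Lmax=int(Lmax), index_list=idx, ntot=len(idx))


_coupling_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def build_coupling_matrices(basis: SleBasis) -> tuple[np.ndarray, np.ndarray]:
    """Offset-coupling matrices ``C0`` and ``C2`` over the symmetrized basis.

    ``[C0]_{LM,lm} = <2 0 l m|L M> <2 0 l 0|L 0>`` (nonzero only for
    ``m = M``) and
    ``[C2]_{LM,lm} = (1 + delta_{M0}) (<2 -2 l m|L M> + <2 2 l m|L M>)
    <2 0 l 0|L 0>``.
    The factor of 2 on the ``M = 0`` rows compensates the symmetrization of
    the ``+/-M`` coefficients, of which ``M = 0`` is its own partner.
    """
    if basis.Lmax in _coupling_cache:
        return _coupling_cache[basis.Lmax]
    n = basis.ntot
    C0 = np.zeros((n, n))
    C2 = np.zeros((n, n))
    for a, (L, M) in enumerate(basis.index_list):
        for b, (l, m) in enumerate(basis.index_list):
            proj = clebsch_gordan(2, 0, l, 0, L, 0)
            if proj == 0.0:
                continue
            if m == M:
                C0[a, b] = clebsch_gordan(2, 0, l, m, L, M) * proj
            cpm = (clebsch_gordan(2, -2, l, m, L, M)
                   + clebsch_gordan(2, 2, l, m, L, M))
            if cpm != 0.0:
                C2[a, b] = (2.0 if M == 0 else 1.0) * cpm * proj
    _coupling_cache[basis.Lmax] = (C0, C2)
    return C0, C2


@dataclass(frozen=True)
class SleOperatorSet:
    """All matrices of the expanded Bloch dynamics for one parameter set.

    Diagonals are stored as vectors: ``cd = L(L+1)``,
    ``r1_diag = R1 + D_rot*cd`` and ``r2_diag = R2 + D_rot*cd`` (1/s).  The
    offset block is ``delta(D) = D*E + W`` with
    ``W = gamma02*C0 + gamma22*C2``.
    """

    basis: SleBasis
    spin: SpinSystemParams
    rot: RotationalDiffusion
    gamma02: float
    gamma22: float
    C0: np.ndarray = field(repr=False)
    C2: np.ndarray = field(repr=False)
    cd: np.ndarray = field(repr=False)
    r1_diag: np.ndarray = field(repr=False)
    r2_diag: np.ndarray = field(repr=False)
    W: np.ndarray = field(repr=False)

    @property
    def ntot(self) -> int:
        return self.basis.ntot

    # -- offset-dependent stacks -------------------------------------------
    def delta_stack(self, offsets: np.ndarray) -> np.ndarray:
        """Offset matrices ``Delta*E + W`` stacked over offsets."""
        offs = np.atleast_1d(np.asarray(offsets, dtype=float))
        n = self.ntot
        out = np.broadcast_to(self.W, (offs.size, n, n)).copy()
        ii = np.arange(n)
        out[:, ii, ii] += offs[:, None]
        return out

    def _p_quadratic(self, diag_r2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Coefficient matrices of ``P(D) = A0 + D*A1 + D^2*A2`` for a given
        (possibly complex) relaxation diagonal in ``Delta R2^-1 Delta``."""
        inv2 = 1.0 / diag_r2
        W = self.W
        A2 = np.diag(inv2)
        A1 = inv2[:, None] * W + W * inv2[None, :]
        A0 = W @ (inv2[:, None] * W)
        return A0, A1, A2

    def p0_stack(self, offsets: np.ndarray) -> np.ndarray:
        """Real matrices ``P0(D) = R2 + w1^2 R1^-1 + Delta R2^-1 Delta``."""
        offs = np.atleast_1d(np.asarray(offsets, dtype=float))
        w1 = self.spin.omega1
        base = np.diag(self.r2_diag + w1 ** 2 / self.r1_diag)
        A0, A1, A2 = self._p_quadratic(self.r2_diag)
        return ((base + A0)[None] + offs[:, None, None] * A1[None]
                + (offs ** 2)[:, None, None] * A2[None])

    def p_stack(self, offsets: np.ndarray) -> np.ndarray:
        """Complex matrices ``P(D)`` with ``i*omega_I`` on the relaxation
        diagonals (the coherence-space generalization of ``P0``)."""
        offs = np.atleast_1d(np.asarray(offsets, dtype=float))
        w1 = self.spin.omega1
        zi = 1j * self.spin.omega_I
        r1c = self.r1_diag + zi
        r2c = self.r2_diag + zi
        base = np.diag(r2c + w1 ** 2 / r1c)
        A0, A1, A2 = self._p_quadratic(r2c)
        return ((base + A0)[None] + offs[:, None, None] * A1[None]
                + (offs ** 2)[:, None, None] * A2[None])

    def dp0_stack(self, offsets: np.ndarray) -> np.ndarray:
        """Analytic offset derivative ``dP0/dD = R2^-1 Delta + Delta R2^-1``."""
        offs = np.atleast_1d(np.asarray(offsets, dtype=float))
        inv2 = 1.0 / self.r2_diag
        W = self.W
        A1 = inv2[:, None] * W + W * inv2[None, :]
        n = self.ntot
        out = np.broadcast_to(A1, (offs.size, n, n)).copy()
        ii = np.arange(n)
        out[:, ii, ii] += 2.0 * offs[:, None] * inv2[None, :]
        return out

    def bigb_stack(self, offsets: np.ndarray, omega_i: float,
                   omega1: float | None = None) -> np.ndarray:
        """Full ``3*ntot`` matrices ``B = B0 + i*omega_i`` stacked over
        offsets, in (x, y, z) block order."""
        offs = np.atleast_1d(np.asarray(offsets, dtype=float))
        n = self.ntot
        w1 = self.spin.omega1 if omega1 is None else omega1
        m = offs.size
        B = np.zeros((m, 3 * n, 3 * n), dtype=complex)
        ii = np.arange(n)
        dm = self.delta_stack(offs)
        zi = 1j * omega_i
        B[:, ii, ii] = self.r2_diag + zi
        B[:, n + ii, n + ii] = self.r2_diag + zi
        B[:, 2 * n + ii, 2 * n + ii] = self.r1_diag + zi
        B[:, 0:n, n:2 * n] = dm
        B[:, n:2 * n, 0:n] = -dm
        B[:, n + ii, 2 * n + ii] = w1
        B[:, 2 * n + ii, n + ii] = -w1
        return B


def build_sle_operators(basis: SleBasis | int, spin: SpinSystemParams,
                        rot: RotationalDiffusion,
                        gamma02: float, gamma22: float) -> SleOperatorSet:
    """Assemble the operator set for one parameter combination.

    ``basis`` may be a :class:`SleBasis` or an even ``Lmax``.
    """
    if isinstance(basis, (int, np.integer)):
        basis = build_basis(int(basis))
    if not np.isfinite(gamma02) or not np.isfinite(gamma22):
        raise InvalidParameterError("anisotropy frequencies must be finite")
    C0, C2 = build_coupling_matrices(basis)
    Ls = np.array([L for L, _ in basis.index_list], dtype=float)
    cd = Ls * (Ls + 1.0)
    return SleOperatorSet(
        basis=basis, spin=spin, rot=rot,
        gamma02=float(gamma02), gamma22=float(gamma22),
        C0=C0, C2=C2, cd=cd,
        r1_diag=spin.R1 + rot.D_rot * cd,
        r2_diag=spin.R2 + rot.D_rot * cd,
        W=gamma02 * C0 + gamma22 * C2,
    )


@dataclass(frozen=True)
class EprResult:
    """Per-offset cw-EPR quantities: absorption, dispersion, saturation."""

    offsets: np.ndarray
    abs: np.ndarray
    dsp: np.ndarray
    s: np.ndarray


def _e1(m: int, n: int, dtype=float) -> np.ndarray:
    e = np.zeros((m, n), dtype=dtype)
    e[:, 0] = 1.0
    return e


def epr_slow_tumbling(offsets, ops: SleOperatorSet,
                      method: str = "reduced") -> EprResult:
    """Steady-state cw-EPR spectrum and saturation under slow tumbling.

    ``method='reduced'`` inverts the ``ntot x ntot`` matrix ``P0`` per
    offset; ``method='full'`` solves the dense ``3*ntot`` steady state as a
    cross-check.  At every offset ``s = -omega1*T1e*abs`` holds exactly.
    """
    offs = np.atleast_1d(np.asarray(offsets, dtype=float))
    if not np.all(np.isfinite(offs)):
        raise InvalidParameterError("offsets must be finite")
    spin = ops.spin
    w1 = spin.omega1
    n = ops.ntot
    if method == "reduced":
        P0 = ops.p0_stack(offs)
        x = np.linalg.solve(P0, _e1(offs.size, n)[..., None])[..., 0]
        absorption = -w1 * x[:, 0]
        dm = ops.delta_stack(offs)
        dsp = w1 * spin.T2e * np.einsum("mj,mj->m", dm[:, 0, :], x)
        sat = -w1 * spin.T1e * absorption
    elif method == "full":
        B = ops.bigb_stack(offs, 0.0).real
        rhs = np.zeros((offs.size, 3 * n))
        rhs[:, 2 * n] = spin.R1  # R1 * |00> in the z block (szeq = 1)
        sol = np.linalg.solve(B, rhs[..., None])[..., 0]
        dsp = sol[:, 0]
        absorption = sol[:, n]
        sat = 1.0 - sol[:, 2 * n]
    else:  # pragma: no cover - defensive
        raise ValueError(f"unknown method {method!r}")
    return EprResult(offsets=offs, abs=absorption, dsp=dsp, s=sat)


def epr_derivative_spectrum(offsets, ops: SleOperatorSet,
                            phi: float = 0.0) -> np.ndarray:
    """Derivative-mode cw-EPR signal with dispersion admixture.

    Returns ``(d sy00 / dD) cos(phi) + (d sx00 / dD) sin(phi)`` using the
    analytic derivative ``dP0/dD = R2^-1 Delta + Delta R2^-1`` (no finite
    differencing).
    """
    offs = np.atleast_1d(np.asarray(offsets, dtype=float))
    if not np.all(np.isfinite(offs)) or not np.isfinite(phi):
        raise InvalidParameterError("offsets and phi must be finite")
    spin = ops.spin
    w1 = spin.omega1
    n = ops.ntot
    P0 = ops.p0_stack(offs)
    x = np.linalg.solve(P0, _e1(offs.size, n)[..., None])[..., 0]  # P0^-1 |00>
    Dp = ops.dp0_stack(offs)
    dsy = w1 * np.linalg.solve(P0, np.einsum("mij,mj->mi", Dp, x)[..., None])[..., 0]
    sy = -w1 * x
    dm = ops.delta_stack(offs)
    dsx = -(1.0 / ops.r2_diag)[None, :] * (
        sy + np.einsum("mij,mj->mi", dm, dsy)
    )
    return dsy[:, 0] * np.cos(phi) + dsx[:, 0] * np.sin(phi)
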