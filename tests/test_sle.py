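"""SLE engine: basis, coupling matrices, slow-motional EPR spectra."""

import numpy as np
import pytest
from scipy.special import roots_legendre, sph_harm_y

from dnpliq import (
    GTensor,
    InvalidParameterError,
    RotationalDiffusion,
    SpinSystemParams,
    bloch_steady_state,
    build_basis,
    build_coupling_matrices,
    build_sle_operators,
    clebsch_gordan,
    epr_derivative_spectrum,
    epr_slow_tumbling,
    gamma_anisotropies,
    gtensor_from_anisotropies,
)
from dnpliq.constants import TWO_PI, mhz_to_angular

from conftest import GAMMA02, GAMMA22


class TestGammaAnisotropies:
    def test_nitroxide_reference_values(self):
        """g = diag(2.00755, 2.00555, 2.0023) at 9.403 T gives
        (gamma0, gamma2)/2pi = (-373, 107) MHz."""
        g = GTensor(2.00755, 2.00555, 2.0023)
        g02, g22 = gamma_anisotropies(g, 9.403)
        assert round(g02 / TWO_PI / 1e6) == -373
        assert round(g22 / TWO_PI / 1e6) == 107

    def test_isotropic_tensor(self):
        g02, g22 = gamma_anisotropies(GTensor(2.005, 2.005, 2.005), 9.403)
        assert g02 == 0.0 and g22 == 0.0

    def test_axial_tensor(self):
        _, g22 = gamma_anisotropies(GTensor(2.006, 2.006, 2.0023), 9.403)
        assert g22 == 0.0

    def test_inverse_recovers_principal_values(self):
        g = gtensor_from_anisotropies(GAMMA02, GAMMA22, 9.4029, gzz=2.0023)
        assert g.gxx == pytest.approx(2.00755, abs=2e-5)
        assert g.gyy == pytest.approx(2.00555, abs=2e-5)


class TestClebschGordan:
    @pytest.mark.parametrize("args, expected", [
        ((2, 0, 0, 0, 2, 0), 1.0),
        ((2, 0, 2, 0, 0, 0), 1.0 / np.sqrt(5.0)),
        ((2, 2, 0, 0, 2, 2), 1.0),
        ((2, 0, 2, 0, 3, 0), 0.0),  # parity-forbidden
        ((2, 1, 2, 0, 2, 0), 0.0),  # projection rule
        ((2, 0, 4, 0, 8, 0), 0.0),  # triangle rule
    ])
    def test_reference_coefficients(self, args, expected):
        assert clebsch_gordan(*args) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("j1, m1, j2, m2", [(2, 0, 2, 2), (2, -2, 4, 0)])
    def test_unitarity(self, j1, m1, j2, m2):
        total = sum(
            clebsch_gordan(j1, m1, j2, m2, J, m1 + m2) ** 2
            for J in range(abs(j1 - j2), j1 + j2 + 1)
        )
        assert total == pytest.approx(1.0, rel=1e-12)

    def test_bad_arguments(self):
        with pytest.raises(InvalidParameterError):
            clebsch_gordan(2, 0.3, 2, 0, 2, 0)
        with pytest.raises(InvalidParameterError):
            clebsch_gordan(-2, 0, 2, 0, 2, 0)


class TestBasis:
    @pytest.mark.parametrize("Lmax, ntot", [(0, 1), (2, 3), (8, 15),
                                            (12, 28), (16, 45)])
    def test_counting(self, Lmax, ntot):
        basis = build_basis(Lmax)
        assert basis.ntot == ntot
        assert basis.ntot == Lmax ** 2 / 8 + 3 * Lmax / 4 + 1

    def test_ordering(self):
        basis = build_basis(4)
        assert basis.index_list == ((0, 0), (2, 0), (2, 2), (4, 0), (4, 2),
                                    (4, 4))

    @pytest.mark.parametrize("bad", [3, -2, 2.5])
    def test_invalid_lmax(self, bad):
        with pytest.raises(InvalidParameterError):
            build_basis(bad)


def _wigner_triple_product(L, M, K, l, m, nodes):
    """Numerical (2L+1)/(8 pi^2) * Int conj(D^L_{M0}) D^2_{K0} D^l_{m0} dOmega
    via Gauss-Legendre in cos(beta) and a uniform alpha grid.  Independent
    oracle for the Clebsch-Gordan product of the coupling matrices."""
    x, w, alpha = nodes
    beta = np.arccos(x)

    def Y(ll, mm):
        if abs(mm) > ll:
            return np.zeros((beta.size, alpha.size), dtype=complex)
        return sph_harm_y(ll, mm, beta[:, None], alpha[None, :])

    integrand = Y(L, M) * np.conj(Y(2, K)) * np.conj(Y(l, m))
    inner = integrand.sum(axis=1) * (2.0 * np.pi / alpha.size)
    val = (w * inner).sum()
    pref = (2 * L + 1) / (4.0 * np.pi) * (4.0 * np.pi) ** 1.5 / np.sqrt(
        (2 * L + 1) * 5.0 * (2 * l + 1)
    )
    return (pref * val).real


class TestCouplingMatrices:
    def test_lmax2_reference_entries(self):
        """The printed Lmax = 2 matrices, including the factor-2 exception
        on the M = 0 rows of C2."""
        C0, C2 = build_coupling_matrices(build_basis(2))
        expect_C0 = np.array([
            [0.0, 1.0 / 5.0, 0.0],
            [1.0, 2.0 / 7.0, 0.0],
            [0.0, 0.0, -2.0 / 7.0],
        ])
        expect_C2 = np.array([
            [0.0, 0.0, 2.0 / 5.0],
            [0.0, 0.0, -4.0 / 7.0],
            [1.0, -2.0 / 7.0, 0.0],
        ])
        assert np.allclose(C0, expect_C0, atol=1e-14)
        assert np.allclose(C2, expect_C2, atol=1e-14)

    def test_rank2_selection_rules(self):
        basis = build_basis(10)
        C0, C2 = build_coupling_matrices(basis)
        for a, (L, M) in enumerate(basis.index_list):
            for b, (l, m) in enumerate(basis.index_list):
                if abs(L - l) > 2:
                    assert C0[a, b] == 0.0 and C2[a, b] == 0.0
                if m != M:
                    assert C0[a, b] == 0.0
                if abs(m - M) != 2:
                    assert C2[a, b] == 0.0

    def test_against_wigner_quadrature_oracle(self):
        """Lmax = 10 matrices agree with brute-force numerical quadrature
        of the triple-Wigner integral to 1e-8."""
        basis = build_basis(10)
        C0, C2 = build_coupling_matrices(basis)
        x, w = roots_legendre(40)
        nodes = (x, w, np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False))
        n = basis.ntot
        C0q = np.zeros((n, n))
        C2q = np.zeros((n, n))
        for a, (L, M) in enumerate(basis.index_list):
            for b, (l, m) in enumerate(basis.index_list):
                if abs(L - l) > 2:
                    continue
                if m == M:
                    C0q[a, b] = _wigner_triple_product(L, M, 0, l, m, nodes)
                if abs(m - M) == 2:
                    val = (_wigner_triple_product(L, M, -2, l, m, nodes)
                           + _wigner_triple_product(L, M, 2, l, m, nodes))
                    C2q[a, b] = (2.0 if M == 0 else 1.0) * val
        assert np.max(np.abs(C0 - C0q)) < 1e-8
        assert np.max(np.abs(C2 - C2q)) < 1e-8


class TestOperators:
    def test_tumbling_diagonal(self, epr_spin, make_ops):
        ops = make_ops(epr_spin, Lmax=2)
        assert np.allclose(ops.cd, [0.0, 6.0, 6.0])
        D = ops.rot.D_rot
        assert ops.r2_diag[1] == pytest.approx(epr_spin.R2 + 6.0 * D)

    def test_lmax0_is_scalar(self, epr_spin, make_ops):
        ops = make_ops(epr_spin, Lmax=0)
        assert ops.ntot == 1
        assert ops.C0.shape == (1, 1) and ops.C0[0, 0] == 0.0

    def test_tau_drot_convention(self):
        rot = RotationalDiffusion.from_tau(5e-9)
        assert rot.tau_rot * 6.0 * rot.D_rot == pytest.approx(1.0, rel=1e-14)


class TestEprSpectrum:
    def test_lmax0_reduces_to_bloch(self, dnp_spin, make_ops, rng):
        """With a single basis function the engine is the Bloch equations."""
        ops = make_ops(dnp_spin, Lmax=0)
        offs = rng.uniform(-5e9, 5e9, size=200)
        res = epr_slow_tumbling(offs, ops)
        ref = bloch_steady_state(offs, dnp_spin)
        for x, y in ((res.abs, ref.abs), (res.dsp, ref.dsp), (res.s, ref.s)):
            assert np.max(np.abs(x - y)) < 1e-12 * np.max(np.abs(y))

    def test_reduced_equals_full_solve(self, dnp_spin, make_ops):
        ops = make_ops(dnp_spin, tau_rot=5e-9, Lmax=10)
        offs = mhz_to_angular(np.linspace(-600.0, 600.0, 61))
        a = epr_slow_tumbling(offs, ops, method="reduced")
        b = epr_slow_tumbling(offs, ops, method="full")
        for x, y in ((a.abs, b.abs), (a.dsp, b.dsp), (a.s, b.s)):
            assert np.max(np.abs(x - y)) < 1e-9 * np.max(np.abs(y))

    @pytest.mark.parametrize("Lmax", [0, 2, 8])
    def test_saturation_proportional_to_absorption(self, dnp_spin, make_ops,
                                                   Lmax):
        """s = -omega1*T1e*abs at every offset and truncation order."""
        ops = make_ops(dnp_spin, Lmax=Lmax)
        offs = mhz_to_angular(np.linspace(-700.0, 700.0, 201))
        res = epr_slow_tumbling(offs, ops)
        expected = -dnp_spin.omega1 * dnp_spin.T1e * res.abs
        assert np.allclose(res.s, expected, rtol=1e-12)
        assert np.all((res.s >= 0.0) & (res.s < 1.0))

    def test_lmax_convergence_for_moderate_tumbling(self, epr_spin, make_ops):
        """Truncation convergence: Lmax = 8 agrees with Lmax = 10 within 1%
        of the peak at the fitted tumbling times, and Lmax = 10 is itself
        converged (vs Lmax = 12) to a few per mille even at 10 ns."""
        offs = mhz_to_angular(np.linspace(-700.0, 700.0, 351))
        for tau in (1.9e-9, 5.2e-9):
            a = epr_slow_tumbling(offs, make_ops(epr_spin, tau, Lmax=8)).abs
            b = epr_slow_tumbling(offs, make_ops(epr_spin, tau, Lmax=10)).abs
            assert np.max(np.abs(a - b)) < 0.01 * np.max(np.abs(b))
        a = epr_slow_tumbling(offs, make_ops(epr_spin, 10e-9, Lmax=10)).abs
        b = epr_slow_tumbling(offs, make_ops(epr_spin, 10e-9, Lmax=12)).abs
        assert np.max(np.abs(a - b)) < 0.005 * np.max(np.abs(b))

    def test_motional_narrowing_limit(self, epr_spin, make_ops):
        """As tau_rot -> 0 the peak-normalized line tends to a Lorentzian of
        width 2/T2 (< 2% shape deviation at 1 ps)."""
        offs = mhz_to_angular(np.linspace(-700.0, 700.0, 701))
        sim = epr_slow_tumbling(offs, make_ops(epr_spin, 1e-12, Lmax=4)).abs
        ref = bloch_steady_state(offs, epr_spin).abs
        sim = sim / np.max(np.abs(sim))
        ref = ref / np.max(np.abs(ref))
        assert np.max(np.abs(sim - ref)) < 0.02


class TestDerivativeSpectrum:
    def test_pure_in_phase_at_zero_mixing(self, epr_spin, make_ops):
        ops = make_ops(epr_spin, Lmax=8)
        offs = mhz_to_angular(np.linspace(-500.0, 500.0, 101))
        h = 1e3
        analytic = epr_derivative_spectrum(offs, ops, phi=0.0)
        fd = (epr_slow_tumbling(offs + h, ops).abs
              - epr_slow_tumbling(offs - h, ops).abs) / (2.0 * h)
        assert np.max(np.abs(analytic - fd)) < 1e-6 * np.max(np.abs(analytic))

    def test_lorentzian_derivative_at_low_power(self):
        """Lmax = 0, w1 -> 0: the analytic derivative of the Lorentzian
        absorption -omega1*R2/(R2^2 + D^2)... differentiated in D."""
        spin = SpinSystemParams(B0=9.403, B1=1e-6, T1e=100e-9, T2e=20e-9)
        ops = build_sle_operators(0, spin, RotationalDiffusion.from_tau(5e-9),
                                  0.0, 0.0)
        offs = np.linspace(-3e8, 3e8, 41)
        got = epr_derivative_spectrum(offs, ops, phi=0.0)
        w1, T2, R2 = spin.omega1, spin.T2e, spin.R2
        expected = 2.0 * w1 * offs * T2 / (R2 + offs ** 2 * T2) ** 2
        assert np.max(np.abs(got - expected)) < 1e-9 * np.max(np.abs(expected))

    def test_mixing_angle_combines_components(self, epr_spin, make_ops):
        ops = make_ops(epr_spin, Lmax=4)
        offs = mhz_to_angular(np.linspace(-500.0, 500.0, 21))
        d0 = epr_derivative_spectrum(offs, ops, phi=0.0)
        d90 = epr_derivative_spectrum(offs, ops, phi=np.pi / 2.0)
        phi = np.radians(-15.0)
        mixed = epr_derivative_spectrum(offs, ops, phi=phi)
        assert np.allclose(mixed, d0 * np.cos(phi) + d90 * np.sin(phi),
                           rtol=1e-10)

    def test_derivative_integrates_to_zero(self, epr_spin, make_ops):
        ops = make_ops(epr_spin, tau_rot=5.2e-9, Lmax=10)
        offs = mhz_to_angular(np.linspace(-1500.0, 1500.0, 1501))
        deriv = epr_derivative_spectrum(offs, ops, phi=0.0)
        integral = np.trapezoid(deriv, offs)
        scale = np.trapezoid(np.abs(deriv), offs)
        assert abs(integral) < 1e-3 * scale
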