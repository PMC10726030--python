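# Methods

`dnpliq` simulates and fits continuous-wave EPR spectra and mixed
Overhauser-effect (OE) / solid-effect (SE) DNP enhancement profiles of
slowly tumbling nitroxide-like radicals in viscous liquids at high
magnetic field, and converts the fitted amplitudes into molecular
quantities.  This note records the models, the numerical choices, and the
limits of what the synthetic-data tests demonstrate.

## Spin model

The electronic spin is described by the classical Bloch equations in the
rotating frame, with spin-lattice and spin-spin rates `R1 = 1/T1e`,
`R2 = 1/T2e`, Rabi frequency `omega1 = g0*muB*B1/hbar` and offset `Delta`
between the electronic Larmor frequency and the microwave frequency.  The
quoted `B1` values (0.02 G for cw-EPR, 5.5 G for DNP) are treated as
rotating-frame amplitudes; no factor-1/2 linear-field conversion is
applied.  All offsets are angular frequencies internally; file axes are
ordinary frequency in MHz.  Magnetizations are stored relative to the
thermal electronic magnetization, which never appears explicitly — every
observable (absorption, dispersion, saturation factor, enhancement) is a
ratio.

The steady state gives the absorptive and dispersive cw-EPR components and
the saturation factor `s`, with the exact identity `s = -omega1*T1e*abs`
valid at all powers.

### Solid-effect rates

The electron–nucleus dipolar coupling drives "forbidden" zero- and
double-quantum flips.  Their effect on the nuclear polarization is carried
by two offset-dependent rate constants: `v+` (microwave contribution to
nuclear relaxation, even in `Delta` for a symmetric line) and `p*v-`
(polarization transfer, odd in `Delta`), obtained from the steady state of
the electron–nucleus coherences, whose relaxation matrix is the Bloch
matrix shifted by `i*omega_I` on the diagonal.  Closed forms exist for a
homogeneous line; a numerically inverted coherence matrix provides an
independent route, and the two are cross-checked to 1e-10 in the tests.

The SE enhancement is `eps = p*v- * T1I / (1 + v+*T1I) * |gamma_S|/gamma_I`;
since `v+/<delta^2>` is of order 1 ps and `<delta^2>*T1I` of order 1/ns,
`v+*T1I ~ 1e-3` and the multiplicative approximation (dropping the
denominator) is used throughout the fitting, as the tests verify.

### Translational diffusion (FFHS)

In liquids the dipolar coupling fluctuates through relative translational
diffusion, modeled as force-free hard spheres with contact distance `b`
and timescale `tau = b^2/D`.  The reduced spectral density

    j11(s) = tau * (x + 4) / (x^3 + 4x^2 + 9x + 9),   x = sqrt(s*tau)

(principal branch) replaces the inverse of the coherence relaxation matrix
by the matrix function `Q = j11(B)`, evaluated by eigendecomposition:
`B U = U diag(lambda)`, `Q = U diag(j11(lambda)) U^{-1}`.  Relaxation
matrices have eigenvalues with non-negative real parts, so the square-root
branch cut is never crossed; tiny negative real parts from round-off are
clipped to the imaginary axis.  An eigenvector condition number above 1e8
triggers one retry at a 1e-8-relatively perturbed offset, then an error —
`B` is non-normal and exact degeneracies occur only on measure-zero
parameter sets.  The dipolar amplitude enters only through the scale
`<delta^2> = Ddip^2 * (6 pi/5) * N / (3 b^3)`, so all line-shape
computations are run at unit scale and amplitudes are attached afterwards.

### Slow tumbling (anisotropic g tensor)

At 9.4 T the nitroxide EPR width is dominated by the g-tensor anisotropy,
summarized by two secular frequencies

    gamma02 = (2/3) [gzz - (gxx+gyy)/2] muB B0 / hbar,
    gamma22 = (gxx - gyy)/sqrt(6) muB B0 / hbar,

about -373 and +107 MHz for a typical nitroxide at 9.4 T.  The hyperfine
tensor and the non-secular response to the g anisotropy are neglected; this
limits the model to high fields.

Isotropic rotational diffusion (`tau_rot = 1/(6*D_rot)`, the rank-2
convention) is handled by expanding the orientation dependence of the spin
observables in Wigner rotation functions.  Symmetry restricts the
surviving coefficients to even `L <= Lmax`, even `0 <= M <= L`
(`ntot = Lmax^2/8 + 3Lmax/4 + 1` of them), turning every Bloch-matrix
element into an `ntot x ntot` block: relaxation and tumbling stay diagonal
(`R_{1,2} + D_rot L(L+1)`), and only the offset block
`Delta*E + gamma02*C0 + gamma22*C2` mixes `(L, M)` levels.  The coupling
matrices are products of Clebsch–Gordan coefficients, computed exactly
with sympy and cached; the symmetrization of `+M` and `-M` coefficients
doubles the `M = 0` rows of `C2` (an `M = 0` coefficient is its own
symmetrization partner).  The implementation was validated against an
independent unsymmetrized solver over the full `-L..L` index range and
against numerical quadrature of the triple-Wigner-function integral.

Spectra and SE rates then follow from the same expressions as in the
homogeneous case with scalars promoted to blocks: the steady state needs
only the inverse of an `ntot x ntot` matrix `P0` (and its `+i*omega_I`
counterpart `P` for the rates); dense `3*ntot` solves are retained as
cross-check routes.  Derivative-mode spectra use the analytic derivative
of `P0` with respect to the offset, with an adjustable dispersion-mixing
angle `phi`.  For the liquid-state rates the matrix function `j11(B)` is
taken of the full `3*ntot` coherence matrix per offset; everything is
batched over offsets with stacked `numpy.linalg` calls.

Truncation: `Lmax = 8` (15 basis functions) keeps the spectrum within 1%
of the `Lmax = 10` reference for the tumbling times encountered in the
fits (1.9–5.2 ns); the measured `Lmax = 8` truncation error grows to
~1.7% of peak by `tau_rot = 10 ns`, where `Lmax = 10` itself is still
converged to ~0.25% (vs `Lmax = 12`).  Simulation commands therefore
default to `Lmax = 10`; fitting and fixture generation default to
`Lmax = 8` for speed.

## Mixed DNP spectrum and fitting

The mixed enhancement profile is modeled as

    eps(Delta) = -sigma_OE * s(Delta - shift)
                 + sigma_SE * (p v- / <delta^2>)(Delta - shift)

The saturation profile carries the power-broadened OE line shape (OE from
dipolar coupling is negative, hence the explicit sign, keeping the stored
`sigma_OE` positive); the SE term is positive near `+omega_I`.  The
horizontal shift absorbs the imprecisely known static field.

Fitting is trust-region least squares (`scipy.optimize.least_squares`,
bounds, unweighted sum of squares).  Linear parameters — the overall EPR
amplitude, and `sigma_OE`/`sigma_SE` — are profiled out by exact linear
least squares inside the residual (variable projection), so the nonlinear
search is over `(gamma02, gamma22, log tau_rot, phi, shift)` for EPR and
`(log tau_ffhs, log T1e, shift)` for DNP.  Time constants are searched in
log space with bounds (`tau_rot` in [0.01, 100] ns, `tau_ffhs` in
[0.3, 100] ns, `T1e` in [10, 2000] ns, `|phi| <= 15 deg`,
`|shift| <= 100 MHz`).  Derivative EPR spectra have a rugged landscape in
`tau_rot`, so the EPR fit multi-starts from a small log-spaced grid around
the initial guess (3 starts by default).  After variable projection the
DNP landscape is smooth in practice and a single start suffices by
default; `n_starts` raises it.  Any parameter can be fixed, as done when
transferring the g tensor and `tau_rot` from the EPR stage to the DNP
stage, or when pinning `tau_ffhs`.

Field-swept data are converted to offset axes via
`Delta(B) = g_ref*muB*B/hbar - 2*pi*mw_freq`; the residual reference
ambiguity is absorbed by the fitted shift.

## Derived molecular parameters

From the fitted amplitudes: leakage factor `f = 1 - T1I/T1I0`; coupling
factor `c = (sigma_OE/f) * gamma_I/|gamma_S|`; dipolar strength
`<delta^2>*T1I = sigma_SE * gamma_I/|gamma_S|`; contact distance `b` by
inverting the `<delta^2>(b, N)` relation with the spin number density `N`
(e.g. one label per 20 lipids of 1.3 nm^3, i.e. 64 mM); diffusion
coefficient `D = b^2/tau_ffhs`.  With `|gamma_S|/gamma_I = 658.21`
(free electron/proton, overridable) this chain reproduces the reference
values used in the test suite; reported values follow the exact chain
without intermediate rounding, which can differ from doubly rounded
figures by one unit in the last place (e.g. 58.5 vs 59 nm^2/us for the
10-position label).

## Synthetic data

The generator produces the two data kinds the package fits, from the
forward models plus additive Gaussian noise:

* a derivative cw-EPR spectrum at `B1 = 0.02 G` (peak-normalized; noise
  1% of peak), grid ±700 MHz at 2 MHz, and
* a DNP enhancement profile at `B1 = 5.5 G` (noise 0.2 enhancement
  units), grid ±700 MHz at 10 MHz — a scaled-down version of the 2 MHz
  default grid; ~140 points samples the profile about as densely as
  measured ones, and coarser sampling (20 MHz) measurably degrades the
  identifiability of the correlated `(tau_ffhs, sigma_OE)` pair.

Default ground truth is the 10-position doxyl-labeled lipid at 9.4 T:
`gamma02 = -2pi*373 MHz`, `gamma22 = +2pi*107 MHz`, `tau_rot = 5.2 ns`,
`phi = -1.3 deg`, `T2e = 20 ns`; DNP adds `tau_ffhs = 6.4 ns`,
`T1e = 123 ns`, `sigma_OE = 2.43`, `sigma_SE = 1.51/ps`.  Seeds are
explicit and recorded in file headers; identical seeds give byte-identical
files.

What passing the recovery tests shows — and does not show.  The synthetic
profiles come from the same forward model that is fitted, with white
Gaussian noise; recovery therefore demonstrates identifiability and
optimizer correctness under the model, not robustness to the
model-mismatch present in real data (hyperfine structure, anisotropic or
restricted rotation, confined translational diffusion, baseline drifts,
correlated noise).  The recovery statistics at the default noise are:
essentially exact noiseless round-trips; over 20 noise seeds the medians
of `tau_rot` (EPR) and of `sigma_OE`, `sigma_SE`, `tau_ffhs`, `T1e` (DNP)
fall within a few percent of truth, with per-seed spreads of roughly
±5-10% for the DNP parameters.

## Known limitations

* No 14N hyperfine coupling: applicable at high field only.
* Free isotropic rotational diffusion: no ordering potential or
  anisotropic diffusion (no MOMD/SRLS), although the operator structure
  would extend to them.
* Isotropic, unbounded FFHS translation; `b` is an effective parameter,
  not a literal distance of closest approach.
* Steady-state (cw) quantities only; no time-domain build-up.
* The zero- and double-quantum rates enter only through the combinations
  `v+` and `p*v-`; they are not reported separately.
* No uncertainty quantification beyond residuals.
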