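"""Least-squares fitting of cw-EPR derivative spectra and DNP profiles.

The EPR fit varies the g-tensor anisotropy frequencies, the tumbling time,
the dispersion-mixing angle and a horizontal shift; the overall amplitude
is a linear parameter and is profiled out analytically at every step.  The
DNP fit, with the g tensor and tumbling fixed from the EPR stage, varies
the translational timescale, the electronic T1 and a shift; the two
amplitudes ``sigma_OE`` and ``sigma_SE`` are linear and likewise solved by
least squares inside the residual (variable projection), which keeps the
nonlinear search three-dimensional.

Positive time constants are searched in log space with bound constraints;
an optional multi-start over a log-spaced grid of the time constant guards
against the rugged landscape of derivative EPR spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

from .bloch import SpinSystemParams
from .constants import HBAR, MU_B, TWO_PI, mhz_to_angular
from .exceptions import InvalidParameterError
from .ffhs import ffhs_j11
from .sednp import se_rates_slow_liquid
from .sle import RotationalDiffusion, build_sle_operators, epr_derivative_spectrum

__all__ = [
    "SpectrumData",
    "FitResult",
    "convert_field_to_offset",
    "fit_epr",
    "fit_dnp",
]


@dataclass(frozen=True)
class SpectrumData:
    """A measured (or synthetic) spectrum.

    ``axis`` is the offset in MHz (``axis_kind='offset'``) or the field in T
    (``axis_kind='field'``); ``values`` is the signal.  ``kind`` is
    ``'epr_derivative'`` or ``'dnp_enhancement'``.
    """

    axis: np.ndarray
    values: np.ndarray
    kind: str = "epr_derivative"
    axis_kind: str = "offset"

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "values", values)
        if axis.ndim != 1 or axis.shape != values.shape:
            raise InvalidParameterError("axis and values must be matching 1-D arrays")
        if not (np.all(np.isfinite(axis)) and np.all(np.isfinite(values))):
            raise InvalidParameterError("spectrum data must be finite")
        d = np.diff(axis)
        if axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidParameterError("axis must be strictly monotone")
        if self.kind not in ("epr_derivative", "dnp_enhancement"):
            raise InvalidParameterError(f"unknown spectrum kind {self.kind!r}")
        if self.axis_kind not in ("offset", "field"):
            raise InvalidParameterError(f"unknown axis kind {self.axis_kind!r}")

    def offsets_rad(self, mw_freq: float | None = None,
                    g_ref: float = 2.0023) -> np.ndarray:
        """Offset axis in rad/s; field axes require the mw frequency."""
        if self.axis_kind == "offset":
            return mhz_to_angular(self.axis)
        if mw_freq is None:
            raise InvalidParameterError("mw_freq is required for a field axis")
        return convert_field_to_offset(self.axis, mw_freq, g_ref)


def convert_field_to_offset(field, mw_freq: float,
                            g_ref: float = 2.0023) -> np.ndarray:
    """Offset ``Delta(B) = g_ref*muB*B/hbar - 2*pi*mw_freq`` in rad/s.

    Any error in the reference g value is a constant shift absorbed by the
    fitted horizontal translation.
    """
    if mw_freq <= 0.0:
        raise InvalidParameterError("mw_freq must be positive")
    return g_ref * MU_B * np.asarray(field, dtype=float) / HBAR - TWO_PI * mw_freq


@dataclass
class FitResult:
    """Outcome of a nonlinear fit.

    ``params`` maps parameter names to fitted (or fixed) values in SI
    units; ``free`` flags which were varied.  ``fitted_curve`` is the model
    evaluated at the data axis with the final parameters.
    """

    params: dict
    free: dict
    residual_norm: float
    n_evals: int
    success: bool
    fitted_curve: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = []
        for name, val in self.params.items():
            tag = "free " if self.free.get(name, False) else "fixed"
            lines.append(f"{name:>10s} [{tag}] = {_display(name, val)}")
        lines.append(f"residual norm = {self.residual_norm:.6g}  "
                     f"(nfev={self.n_evals}, success={self.success})")
        return "\n".join(lines)


def _display(name: str, val: float) -> str:
    if name in ("gamma02", "gamma22", "shift"):
        return f"{val / (TWO_PI * 1e6):.4g} MHz"
    if name in ("tau_rot", "tau_ffhs", "T1e"):
        return f"{val * 1e9:.4g} ns"
    if name == "phi":
        return f"{np.degrees(val):.4g} deg"
    if name == "sigma_SE":
        return f"{val * 1e-12:.4g} 1/ps"
    return f"{val:.6g}"


_EPR_DEFAULT_SPIN = dict(B0=9.403, B1=0.02, T1e=100e-9, T2e=20e-9)
_DNP_DEFAULT_SPIN = dict(B0=9.403, B1=5.5, T1e=100e-9, T2e=20e-9)

_MHZ = TWO_PI * 1e6

# (default initial value, lower bound, upper bound) in SI units
_EPR_PARAM_SPECS = {
    "gamma02": (-300.0 * _MHZ, -1500.0 * _MHZ, 1500.0 * _MHZ),
    "gamma22": (100.0 * _MHZ, -1500.0 * _MHZ, 1500.0 * _MHZ),
    "tau_rot": (3e-9, 1e-11, 1e-7),
    "phi": (0.0, -np.radians(15.0), np.radians(15.0)),
    "shift": (0.0, -100.0 * _MHZ, 100.0 * _MHZ),
}
_DNP_PARAM_SPECS = {
    "tau_ffhs": (5e-9, 3e-10, 1e-7),
    "T1e": (100e-9, 1e-8, 2e-6),
    "shift": (0.0, -100.0 * _MHZ, 100.0 * _MHZ),
}
_LOG_PARAMS = ("tau_rot", "tau_ffhs", "T1e")


def _pack(name: str, value: float) -> float:
    return np.log10(value) if name in _LOG_PARAMS else value


def _unpack(name: str, value: float) -> float:
    return 10.0 ** value if name in _LOG_PARAMS else value


def _setup_free(specs: dict, init: dict, fixed: dict):
    """Split parameters into free (with packed x0/bounds) and fixed."""
    free_names, x0, lo, hi = [], [], [], []
    values = {}
    for name, (default, lb, ub) in specs.items():
        if name in fixed:
            values[name] = float(fixed[name])
            continue
        start = float(init.get(name, default))
        start = min(max(start, lb), ub)
        free_names.append(name)
        x0.append(_pack(name, start))
        lo.append(_pack(name, lb))
        hi.append(_pack(name, ub))
        values[name] = start
    return free_names, np.array(x0), (np.array(lo), np.array(hi)), values


def _run_multistart(residual: Callable, x0: np.ndarray, bounds, free_names,
                    time_name: str, n_starts: int, max_nfev: int):
    """Run least_squares from ``n_starts`` log-spaced time-constant starts."""
    starts = [x0]
    if n_starts > 1 and time_name in free_names:
        k = free_names.index(time_name)
        span = np.log10(3.0)
        for fac in np.linspace(-span, span, n_starts):
            if fac == 0.0:
                continue
            x = x0.copy()
            x[k] = np.clip(x[k] + fac, bounds[0][k], bounds[1][k])
            starts.append(x)
    best = None
    nfev = 0
    for x in starts:
        res = least_squares(residual, x, bounds=bounds, method="trf",
                            x_scale="jac", max_nfev=max_nfev)
        nfev += res.nfev
        if best is None or res.cost < best.cost:
            best = res
    return best, nfev


def fit_epr(data: SpectrumData, init: dict | None = None,
            fixed: dict | None = None, *,
            spin: SpinSystemParams | None = None, Lmax: int = 8,
            n_starts: int = 3, max_nfev: int = 200,
            mw_freq: float | None = None) -> FitResult:
    """Fit a derivative cw-EPR spectrum.

    Free parameters (any subset may be fixed through ``fixed``):
    ``gamma02``, ``gamma22`` (rad/s), ``tau_rot`` (s), ``phi`` (rad),
    ``shift`` (rad/s) and the linear ``amplitude``.  ``B1``, ``T1e`` and
    ``T2e`` are held at the values in ``spin`` (defaults: 0.02 G, 100 ns,
    20 ns).
    """
    if data.kind != "epr_derivative":
        raise InvalidParameterError("fit_epr expects an epr_derivative spectrum")
    init = dict(init or {})
    fixed = dict(fixed or {})
    if spin is None:
        spin = SpinSystemParams(**_EPR_DEFAULT_SPIN)
    offs = data.offsets_rad(mw_freq)
    y = data.values

    free_names, x0, bounds, values = _setup_free(_EPR_PARAM_SPECS, init, fixed)
    amp_fixed = fixed.get("amplitude")

    def model_and_amp(x):
        p = dict(values)
        for name, xv in zip(free_names, x):
            p[name] = _unpack(name, xv)
        rot = RotationalDiffusion.from_tau(p["tau_rot"])
        ops = build_sle_operators(Lmax, spin, rot, p["gamma02"], p["gamma22"])
        m = epr_derivative_spectrum(offs - p["shift"], ops, p["phi"])
        if amp_fixed is not None:
            a = float(amp_fixed)
        else:
            denom = float(m @ m)
            a = float(m @ y) / denom if denom > 0.0 else 0.0
        return p, a, m

    def residual(x):
        _, a, m = model_and_amp(x)
        return a * m - y

    best, nfev = _run_multistart(residual, x0, bounds, free_names,
                                 "tau_rot", n_starts, max_nfev)
    p, a, m = model_and_amp(best.x)
    p["amplitude"] = a
    free = {k: k in free_names for k in p}
    free["amplitude"] = amp_fixed is None
    return FitResult(params=p, free=free,
                     residual_norm=float(np.linalg.norm(best.fun)),
                     n_evals=nfev, success=bool(best.success),
                     fitted_curve=a * m)


def fit_dnp(data: SpectrumData, init: dict | None = None,
            fixed: dict | None = None, *,
            gamma02: float, gamma22: float, tau_rot: float,
            spin: SpinSystemParams | None = None, Lmax: int = 8,
            n_starts: int = 1, max_nfev: int = 100,
            mw_freq: float | None = None) -> FitResult:
    """Fit a DNP enhancement profile with the mixed OE+SE model.

    The g-tensor anisotropies and the tumbling time come from the EPR
    stage and are fixed.  Free parameters: ``tau_ffhs`` (s), ``T1e`` (s),
    ``shift`` (rad/s) and the linear amplitudes ``sigma_OE``
    (dimensionless) and ``sigma_SE`` (1/s); any may be fixed.
    """
    if data.kind != "dnp_enhancement":
        raise InvalidParameterError("fit_dnp expects a dnp_enhancement spectrum")
    init = dict(init or {})
    fixed = dict(fixed or {})
    if spin is None:
        spin = SpinSystemParams(**_DNP_DEFAULT_SPIN)
    rot = RotationalDiffusion.from_tau(tau_rot)
    offs = data.offsets_rad(mw_freq)
    y = data.values

    free_names, x0, bounds, values = _setup_free(_DNP_PARAM_SPECS, init, fixed)
    sig_oe_fixed = fixed.get("sigma_OE")
    sig_se_fixed = fixed.get("sigma_SE")

    def model_and_sigmas(x):
        p = dict(values)
        for name, xv in zip(free_names, x):
            p[name] = _unpack(name, xv)
        ops = build_sle_operators(Lmax, spin.replace(T1e=p["T1e"]), rot,
                                  gamma02, gamma22)
        rates = se_rates_slow_liquid(offs - p["shift"], ops, 1.0,
                                     ffhs_j11(p["tau_ffhs"]))
        col_oe = -rates.s  # dipolar OE: negative contribution
        col_se = rates.pv_minus  # equals pv-/<delta^2> at unit scale
        target = y.astype(float).copy()
        cols, names = [], []
        if sig_oe_fixed is None:
            cols.append(col_oe)
            names.append("sigma_OE")
        else:
            target -= float(sig_oe_fixed) * col_oe
        if sig_se_fixed is None:
            cols.append(col_se)
            names.append("sigma_SE")
        else:
            target -= float(sig_se_fixed) * col_se
        if cols:
            A = np.column_stack(cols)
            coef, *_ = np.linalg.lstsq(A, target, rcond=None)
            for name, cval in zip(names, coef):
                p[name] = float(cval)
        p.setdefault("sigma_OE", float(sig_oe_fixed or 0.0))
        p.setdefault("sigma_SE", float(sig_se_fixed or 0.0))
        model = p["sigma_OE"] * col_oe + p["sigma_SE"] * col_se
        return p, model

    def residual(x):
        _, model = model_and_sigmas(x)
        return model - y

    best, nfev = _run_multistart(residual, x0, bounds, free_names,
                                 "tau_ffhs", n_starts, max_nfev)
    p, model = model_and_sigmas(best.x)
    free = {k: k in free_names for k in p}
    free["sigma_OE"] = sig_oe_fixed is None
    free["sigma_SE"] = sig_se_fixed is None
    return FitResult(params=p, free=free,
                     residual_norm=float(np.linalg.norm(best.fun)),
                     n_evals=nfev, success=bool(best.success),
                     fitted_curve=model)
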