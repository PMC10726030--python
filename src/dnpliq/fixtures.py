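"""Seeded synthetic-spectrum generator.

Produces forward-model spectra with additive Gaussian noise that emulate
the two kinds of experimental data the package fits: a derivative cw-EPR
spectrum recorded at low microwave power, and a DNP enhancement profile
recorded at high power that mixes a negative Overhauser dip near zero
offset with antisymmetric-like solid-effect features near the nuclear
Larmor frequency (about +/-400 MHz at 9.4 T for protons).

The default ground-truth parameters are those of a 10-position
nitroxide-labeled lipid in a fluid DOPC bilayer at 9.4 T: g-anisotropy
frequencies (-373, 107) MHz, 5.2 ns tumbling, -1.3 deg dispersion mixing
for EPR; 6.4 ns FFHS timescale, 123 ns electronic T1 and amplitudes
sigma_OE = 2.43, sigma_SE = 1.51/ps for DNP.  B1 is 0.02 G (EPR) and
5.5 G (DNP); T2e is 20 ns for both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .bloch import SpinSystemParams
from .constants import TWO_PI, mhz_to_angular
from .exceptions import InvalidParameterError
from .ffhs import ffhs_j11
from .fitting import SpectrumData
from .sednp import EnhancementModelParams, dnp_spectrum_model
from .sle import RotationalDiffusion, build_sle_operators, epr_derivative_spectrum

__all__ = [
    "FixtureSpec",
    "EPR_TRUTH_10DOXYL",
    "DNP_TRUTH_10DOXYL",
    "synth_epr_spectrum",
    "synth_dnp_spectrum",
    "make_fixtures",
]

_MHZ = TWO_PI * 1e6

#: EPR ground truth: 10-position doxyl-labeled lipid at 9.4 T.
EPR_TRUTH_10DOXYL = {
    "gamma02": -373.0 * _MHZ,
    "gamma22": 107.0 * _MHZ,
    "tau_rot": 5.2e-9,
    "phi": np.radians(-1.3),
    "shift": 0.0,
    "amplitude": 1.0,
    "B0": 9.403,
    "B1": 0.02,
    "T1e": 100e-9,
    "T2e": 20e-9,
}

#: DNP ground truth for the same label (high microwave power).
DNP_TRUTH_10DOXYL = {
    "gamma02": -373.0 * _MHZ,
    "gamma22": 107.0 * _MHZ,
    "tau_rot": 5.2e-9,
    "tau_ffhs": 6.4e-9,
    "T1e": 123e-9,
    "sigma_OE": 2.43,
    "sigma_SE": 1.51e12,
    "shift": 0.0,
    "B0": 9.403,
    "B1": 5.5,
    "T2e": 20e-9,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Ground truth, noise levels and seed for one synthetic data set.

    ``noise_epr`` is the Gaussian noise standard deviation as a fraction of
    the EPR peak amplitude; ``noise_dnp`` is in absolute enhancement units.
    The EPR grid is dense (2 MHz steps, like a field sweep); the DNP grid
    uses 10 MHz steps, a scaled-down version of the package's 2 MHz default
    that keeps the liquid-state rate evaluation affordable while sampling
    the enhancement profile about as densely as measured ones.
    """

    epr_truth: dict = field(default_factory=lambda: dict(EPR_TRUTH_10DOXYL))
    dnp_truth: dict = field(default_factory=lambda: dict(DNP_TRUTH_10DOXYL))
    noise_epr: float = 0.01
    noise_dnp: float = 0.2
    seed: int = 0
    Lmax: int = 8
    epr_grid_mhz: tuple = (-700.0, 700.0, 2.0)
    dnp_grid_mhz: tuple = (-700.0, 700.0, 10.0)

    def __post_init__(self) -> None:
        if self.noise_epr < 0.0 or self.noise_dnp < 0.0:
            raise InvalidParameterError("noise levels must be >= 0")


def _grid(spec_mhz: tuple) -> np.ndarray:
    lo, hi, step = spec_mhz
    return np.arange(lo, hi + 0.5 * step, step)


def synth_epr_spectrum(truth: dict | None = None, noise: float = 0.0,
                       seed: int = 0, grid_mhz=None,
                       Lmax: int = 8) -> SpectrumData:
    """Forward-model derivative EPR spectrum, peak-normalized, with optional
    additive Gaussian noise (fraction of the peak amplitude)."""
    t = dict(EPR_TRUTH_10DOXYL)
    t.update(truth or {})
    axis = _grid(grid_mhz or (-700.0, 700.0, 2.0))
    offs = mhz_to_angular(axis)
    spin = SpinSystemParams(B0=t["B0"], B1=t["B1"], T1e=t["T1e"], T2e=t["T2e"])
    ops = build_sle_operators(Lmax, spin, RotationalDiffusion.from_tau(t["tau_rot"]),
                              t["gamma02"], t["gamma22"])
    y = epr_derivative_spectrum(offs - t["shift"], ops, t["phi"])
    peak = np.max(np.abs(y))
    y = t["amplitude"] * y / peak
    if noise > 0.0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise * np.max(np.abs(y)), size=y.shape)
    return SpectrumData(axis=axis, values=y, kind="epr_derivative")


def synth_dnp_spectrum(truth: dict | None = None, noise: float = 0.0,
                       seed: int = 0, grid_mhz=None,
                       Lmax: int = 8) -> SpectrumData:
    """Forward-model DNP enhancement profile with optional additive noise
    (absolute enhancement units)."""
    t = dict(DNP_TRUTH_10DOXYL)
    t.update(truth or {})
    axis = _grid(grid_mhz or (-700.0, 700.0, 10.0))
    offs = mhz_to_angular(axis)
    spin = SpinSystemParams(B0=t["B0"], B1=t["B1"], T1e=t["T1e"], T2e=t["T2e"])
    ops = build_sle_operators(Lmax, spin, RotationalDiffusion.from_tau(t["tau_rot"]),
                              t["gamma02"], t["gamma22"])
    params = EnhancementModelParams(sigma_OE=t["sigma_OE"],
                                    sigma_SE=t["sigma_SE"], shift=t["shift"])
    dnp = dnp_spectrum_model(offs, ops, params, ffhs_j11(t["tau_ffhs"]))
    y = dnp.epsilon
    if noise > 0.0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise, size=y.shape)
    return SpectrumData(axis=axis, values=y, kind="dnp_enhancement")


def make_fixtures(spec: FixtureSpec, outdir) -> dict:
    """Write an EPR and a DNP fixture plus a ground-truth sidecar.

    Returns the paths of the written files.  The same seed always produces
    byte-identical files; the seed is recorded in every header.
    """
    from .io import write_spectrum  # deferred: io imports fitting

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    epr = synth_epr_spectrum(spec.epr_truth, spec.noise_epr, spec.seed,
                             spec.epr_grid_mhz, spec.Lmax)
    # decorrelate the two noise streams while keeping a single user seed
    dnp = synth_dnp_spectrum(spec.dnp_truth, spec.noise_dnp, spec.seed + 1,
                             spec.dnp_grid_mhz, spec.Lmax)
    paths = {
        "epr": outdir / "epr_spectrum.tsv",
        "dnp": outdir / "dnp_spectrum.tsv",
        "truth": outdir / "ground_truth.json",
    }
    write_spectrum(paths["epr"], epr,
                   header={"seed": spec.seed, "noise": spec.noise_epr,
                           "axis units": "MHz"})
    write_spectrum(paths["dnp"], dnp,
                   header={"seed": spec.seed + 1, "noise": spec.noise_dnp,
                           "axis units": "MHz"})
    truth = {
        "version": __version__,
        "seed": spec.seed,
        "Lmax": spec.Lmax,
        "noise_epr": spec.noise_epr,
        "noise_dnp": spec.noise_dnp,
        "epr": spec.epr_truth,
        "dnp": spec.dnp_truth,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, default=float) + "\n")
    return paths
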