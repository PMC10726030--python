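"""Physical constants (CODATA 2018) and small unit helpers.

All internal frequencies in the package are angular (rad/s); the helpers
below convert to/from the ordinary-frequency MHz axes used in output files
and plots.
"""

import numpy as np

MU_B = 9.2740100783e-24  # Bohr magneton, J/T
HBAR = 1.054571817e-34  # reduced Planck constant, J s
MU0_OVER_4PI = 1e-7  # vacuum permeability / 4 pi, SI
AVOGADRO = 6.02214076e23  # 1/mol

GAMMA_E = 1.76085963023e11  # electron gyromagnetic ratio (magnitude), rad/s/T
GAMMA_H = 2.6752218744e8  # proton gyromagnetic ratio, rad/s/T
G_FREE = 2.00231930436  # free-electron g value

#: |gamma_S| / gamma_I for a free electron and a proton (~658.21)
GAMMA_RATIO_EH = GAMMA_E / GAMMA_H

TWO_PI = 2.0 * np.pi


def mhz_to_angular(f):
    """Ordinary frequency in MHz -> angular frequency in rad/s."""
    return TWO_PI * 1e6 * np.asarray(f, dtype=float)


def angular_to_mhz(w):
    """Angular frequency in rad/s -> ordinary frequency in MHz."""
    return np.asarray(w, dtype=float) / (TWO_PI * 1e6)


def gauss_to_tesla(b):
    return np.asarray(b, dtype=float) * 1e-4


def proton_larmor(B0):
    """Proton Larmor angular frequency (rad/s) at static field ``B0`` (T)."""
    return GAMMA_H * B0
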