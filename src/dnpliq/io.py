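"""Delimited-text spectrum I/O and TOML configuration loading.

Spectra are two- or three-column delimited text (whitespace, comma or
semicolon separated) with ``#`` comment lines.  Field-sweep data in this
domain are universally columnar text, so no binary formats are supported.
"""

from __future__ import annotations

import re
import tomllib
from pathlib import Path

import numpy as np

from . import __version__
from .exceptions import ConfigError, SpectrumParseError
from .fitting import SpectrumData

__all__ = ["read_spectrum", "write_spectrum", "load_config"]

_SPLIT = re.compile(r"[,;\s]+")


def read_spectrum(path, axis_kind: str = "offset",
                  kind: str = "epr_derivative") -> SpectrumData:
    """Parse a two/three-column delimited spectrum file.

    Rows are sorted by the axis; a duplicated or otherwise non-strictly
    monotone axis and non-numeric rows raise :class:`SpectrumParseError`
    naming the offending line.
    """
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        parts = [p for p in _SPLIT.split(text) if p]
        if len(parts) < 2:
            raise SpectrumParseError(
                f"{path.name}:{lineno}: expected at least two columns"
            )
        try:
            vals = [float(p) for p in parts[:2]]
        except ValueError as exc:
            raise SpectrumParseError(
                f"{path.name}:{lineno}: non-numeric value ({exc})"
            ) from None
        rows.append((lineno, vals[0], vals[1]))
    if len(rows) < 2:
        raise SpectrumParseError(f"{path.name}: fewer than two data rows")
    axis = np.array([r[1] for r in rows])
    values = np.array([r[2] for r in rows])
    order = np.argsort(axis, kind="stable")
    axis, values = axis[order], values[order]
    dup = np.flatnonzero(np.diff(axis) == 0.0)
    if dup.size:
        lineno = rows[int(order[dup[0] + 1])][0]
        raise SpectrumParseError(
            f"{path.name}:{lineno}: duplicated axis value {axis[dup[0]]:g}"
        )
    return SpectrumData(axis=axis, values=values, kind=kind,
                        axis_kind=axis_kind)


def write_spectrum(path, data: SpectrumData, header: dict | None = None,
                   extra_columns: dict | None = None,
                   delimiter: str = "\t") -> Path:
    """Write a spectrum with a commented header (package version plus any
    parameter echo passed in ``header``)."""
    path = Path(path)
    lines = [f"# dnpliq {__version__}", f"# kind: {data.kind}",
             f"# axis: {data.axis_kind}"]
    for key, val in (header or {}).items():
        lines.append(f"# {key}: {val}")
    names = ["axis", "signal"] + list(extra_columns or {})
    lines.append("# columns: " + ", ".join(names))
    cols = [data.axis, data.values] + [
        np.asarray(c, dtype=float) for c in (extra_columns or {}).values()
    ]
    for row in zip(*cols):
        lines.append(delimiter.join(f"{v:.10g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def load_config(path, required: tuple[str, ...] = ()) -> dict:
    """Load a TOML configuration file and check for required keys
    (dotted paths such as ``"epr.tau_rot"`` are understood)."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    for key in required:
        node = cfg
        for part in key.split("."):
            if not isinstance(node, dict) or part not in node:
                raise ConfigError(f"missing required config key {key!r}")
            node = node[part]
    return cfg
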