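"""Package exception hierarchy."""


class DnpliqError(Exception):
    """Base class for all errors raised by dnpliq."""


class InvalidParameterError(DnpliqError, ValueError):
    """A physical parameter is non-finite, out of range, or inconsistent."""


class NumericalDegeneracyError(DnpliqError, RuntimeError):
    """An eigendecomposition is too ill-conditioned to be trusted."""


class UnstableDynamicsError(DnpliqError, RuntimeError):
    """A relaxation matrix has an eigenvalue with a large negative real part."""


class SpectrumParseError(DnpliqError, ValueError):
    """A spectrum file could not be parsed."""


class ConfigError(DnpliqError, KeyError):
    """A configuration file is missing a required key or has a bad value."""
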