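"""Exception hierarchy."""


class AimpolError(Exception):
    """Base class for all package errors."""


class InputError(AimpolError):
    """Malformed or inconsistent user input (files, config, arguments)."""


class GeometryError(AimpolError):
    """Degenerate or unphysical geometry (zero-volume cell, coincident nuclei)."""


class NumericalError(AimpolError):
    """Non-finite values or numerical breakdown inside an algorithm."""


class ConvergenceError(AimpolError):
    """An iterative solve did not reach its required status."""
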