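"""Exception hierarchy."""


class XCMAX4Error(Exception):
    """Base class for all package errors."""


class ValidationError(XCMAX4Error):
    """Malformed or unusable input data."""


class ConvergenceError(XCMAX4Error):
    """Iterative fit failed to converge."""


class SeparationError(ConvergenceError):
    """Perfect or quasi-perfect separation in a logistic fit."""


class DegenerateStatisticError(XCMAX4Error):
    """No usable genotype signal (all score components degenerate)."""
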