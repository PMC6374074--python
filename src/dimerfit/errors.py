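"""Exception hierarchy shared across the package.

``ValueError`` is still raised directly for plain domain violations
(negative concentrations, fractions outside [0, 1]); the classes here
distinguish the failure modes a pipeline needs to map to exit codes:
bad input data, an unidentifiable or failed fit, and numerical
non-convergence.
"""

__all__ = [
    "DimerfitError",
    "DataError",
    "FitError",
    "NumericalError",
    "TruncatedPeakWarning",
]


class DimerfitError(Exception):
    """Base class for package-specific errors."""


class DataError(DimerfitError, ValueError):
    """Input data is malformed or inconsistent with the calibration."""


class FitError(DimerfitError, RuntimeError):
    """The requested fit is unidentifiable or otherwise cannot proceed."""


class NumericalError(DimerfitError, ArithmeticError):
    """An iterative numerical routine failed to converge."""


class TruncatedPeakWarning(UserWarning):
    """A chromatogram's maximum lies on the trace boundary (truncated peak)."""
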