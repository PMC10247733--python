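"""Exception hierarchy.

All package-raised errors derive from :class:`HaploCycleError` so callers can
catch one base class at pipeline boundaries.
"""


class HaploCycleError(Exception):
    """Base class for all errors raised by haplocycle."""


class ConfigError(HaploCycleError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(HaploCycleError, ValueError):
    """Malformed on-disk input (MTX, GMT, CSV)."""


class ParameterError(HaploCycleError, ValueError):
    """Analysis parameters incompatible with the data (e.g. k >= n_cells)."""


class ContractError(HaploCycleError, ValueError):
    """An input violates a documented precondition (e.g. non-stochastic matrix)."""


class DegenerateDataError(HaploCycleError, ValueError):
    """Data too degenerate for the requested computation (collinear points,
    empty windows, all-equal intensities, zero denominators)."""
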