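"""Exception hierarchy for corticalhue."""


class CorticalHueError(Exception):
    """Base class for all package errors."""


class InputDomainError(CorticalHueError, ValueError):
    """An argument lies outside its documented domain."""


class ConfigError(CorticalHueError, ValueError):
    """A configuration value violates an invariant; the message names the key."""


class DegenerateChromaticityError(CorticalHueError, ValueError):
    """Chromaticity undefined: L + M is zero."""


class AchromaticError(CorticalHueError, ValueError):
    """Hue angle undefined: the chromatic vector relative to white is zero."""


class NoPeakError(CorticalHueError, ValueError):
    """A tuning curve is constant and has no peak."""


class UndefinedBandwidthError(CorticalHueError, ValueError):
    """Response never falls to the half-height threshold within 90 degrees."""


class UndefinedCorrelationError(CorticalHueError, ValueError):
    """Correlation undefined because one variable has zero variance."""
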