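"""Exception hierarchy for the film QA pipeline.

Every stage raises a subclass of :class:`FilmQAError` so the pipeline driver
can attach the stage name and dataset id before re-raising.
"""


class FilmQAError(Exception):
    """Base class for all film QA errors."""


class ExtentError(FilmQAError):
    """A requested plane, point or sphere lies outside the dose-grid extent."""


class DomainError(FilmQAError):
    """Input violates a precondition (empty plane, degenerate region, ...)."""


class ConsistencyError(FilmQAError):
    """Objects that must share geometry or normalization state do not."""


class CalibrationError(FilmQAError):
    """Calibration point set is unusable (non-monotone, duplicated response)."""


class FitError(FilmQAError):
    """Least-squares fit is rank deficient or did not converge."""


class DesignError(FilmQAError):
    """Calibration design violated (e.g. fewer than 3 daily films)."""


class ConversionError(FilmQAError):
    """Too many film pixels fall outside the calibrated response range."""


class GeometryError(FilmQAError):
    """Degenerate landmark configuration or a beam missing the body."""


class NormalizationError(FilmQAError):
    """Normalization dose is non-positive."""


class SpecError(FilmQAError):
    """Analysis criteria/specification parameters are invalid."""


class ParseError(FilmQAError):
    """A file could not be parsed; the message names the offending field."""


class ConfigError(FilmQAError):
    """Pipeline configuration is invalid or references missing files."""


class SimulationError(FilmQAError):
    """The simulator was asked for something unphysical (film saturation...)."""
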