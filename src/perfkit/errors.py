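"""Exception hierarchy.

All perfkit errors derive from :class:`PerfkitError` so callers can catch the
package's failures with a single except clause while letting programming
errors (TypeError etc.) propagate.
"""


class PerfkitError(Exception):
    """Base class for all perfkit errors."""


class InvalidParameterError(PerfkitError, ValueError):
    """A kinetic parameter is outside its physical domain (e.g. T <= 0)."""


class GridError(PerfkitError, ValueError):
    """Two curves do not share a time grid, or a grid is malformed."""


class ConfigError(PerfkitError, ValueError):
    """A preparation / fit / session configuration value is invalid."""


class RoiError(PerfkitError, ValueError):
    """An ROI is empty or lies outside the image bounds."""


class NormalizationError(PerfkitError, ValueError):
    """Signal normalization is impossible (e.g. S0 <= 0 for relative enhancement)."""


class DegenerateFitError(PerfkitError, ValueError):
    """A fit was requested with no free parameters."""


class TimingUnavailableError(PerfkitError, KeyError):
    """The DICOM headers carry none of the timing tags of the requested dialect."""

    def __init__(self, tag: str, dialect: str):
        self.tag = tag
        self.dialect = dialect
        super().__init__(
            f"cannot derive temporal resolution for dialect {dialect!r}: "
            f"required tag {tag} is absent; model calculation is not possible"
        )


class ReadError(PerfkitError, IOError):
    """A DICOM series (or array file) could not be assembled into a 4D volume."""
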