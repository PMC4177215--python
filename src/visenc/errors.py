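"""Exception hierarchy shared across the package.

Configuration problems (bad parameter values, unknown modes) raise
:class:`ConfigurationError`; malformed or inconsistent data raise
:class:`DataError` or one of its subclasses.  The CLI maps the former to
exit code 2 and the latter to exit code 3.
"""


class VisencError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VisencError, ValueError):
    """A parameter or configuration value is invalid."""


class DataError(VisencError, ValueError):
    """Input data are malformed (non-finite values, missing fields, ...)."""


class ShapeError(DataError):
    """An array has the wrong shape or dimensionality."""


class AlignmentError(DataError):
    """Identifiers (stimulus, channel or voxel ids) of two objects disagree."""
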