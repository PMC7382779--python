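"""Exception hierarchy.

Data-shaped problems (malformed files, inconsistent tables) raise
:class:`DataError` subclasses; bad user configuration raises
:class:`ConfigError`. The CLI maps these onto exit codes 1 and 2.
"""


class KinodeltaError(Exception):
    """Base class for all package errors."""


class DataError(KinodeltaError):
    """Malformed or inconsistent input data."""


class FormatError(DataError):
    """A file violates its declared format."""


class DesignError(DataError):
    """A plex design is inconsistent or infeasible."""


class ConfigError(KinodeltaError):
    """Invalid configuration value; message names the offending field."""


class NumericError(KinodeltaError):
    """A numerical operation cannot be carried out (e.g. singular system)."""
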