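"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class RiboassocError(Exception):
    """Base class for all package errors."""


class ConfigError(RiboassocError):
    """Invalid or inconsistent run configuration."""


class DataError(RiboassocError):
    """Malformed or insufficient input data."""


class NoFootprintsError(DataError):
    """A region or transcript carries no usable ribosome footprints."""
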