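"""Exception hierarchy.

``BinbatError`` is the common base; the CLI maps ``ConfigError`` to exit
code 1 and ``DataIntegrityError`` to exit code 2.
"""


class BinbatError(Exception):
    """Base class for all package errors."""


class ConfigError(BinbatError):
    """Invalid configuration or usage."""


class DataIntegrityError(BinbatError):
    """Input data is inconsistent with its own declared structure."""


class ChannelMissingError(DataIntegrityError):
    """A required channel is absent from a file or table."""


class TransformStateError(BinbatError):
    """Attempt to re-transform an already transformed channel."""


class UnsupportedFCSError(DataIntegrityError):
    """FCS file uses a feature outside the supported linear list-mode subset."""


class GatingError(BinbatError):
    """Automated gating could not produce a threshold."""


class UnimodalDensityError(GatingError):
    """Valley thresholding found no usable two-mode structure."""
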