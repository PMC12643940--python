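"""Exception hierarchy for flowscreen.

All errors raised deliberately by the package derive from :class:`FlowscreenError`
so callers can catch pipeline failures without masking programming errors.
"""


class FlowscreenError(Exception):
    """Base class for all flowscreen errors."""


class FormatError(FlowscreenError):
    """A file or table does not conform to its declared format."""


class ConfigurationError(FlowscreenError):
    """A gating strategy, panel or simulation config is invalid or inconsistent."""


class InsufficientDataError(FlowscreenError):
    """An operation requires events/records that are absent (e.g. empty isotype)."""


class QuantificationError(FlowscreenError):
    """A quantification step cannot be carried out (e.g. zero bead events)."""
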