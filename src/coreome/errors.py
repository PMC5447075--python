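"""Exception hierarchy shared across the package."""


class CoreomeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CoreomeError):
    """A table or annotation file violates the expected format."""


class ConfigurationError(CoreomeError):
    """An invalid configuration value; the message names the field."""


class ConsistencyError(CoreomeError):
    """Two inputs that must agree (e.g. share a group universe) do not."""


class CalibrationError(CoreomeError):
    """Threshold calibration has no usable reference measurement."""


class PipelineError(CoreomeError):
    """A pipeline stage failed; the message names the stage and entity."""
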