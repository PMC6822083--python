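"""Exception types shared across the pipeline."""


class PanoutlierError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PanoutlierError, ValueError):
    """A file or table violates its expected on-disk format."""


class ConfigError(PanoutlierError, ValueError):
    """Invalid configuration (dimensions, thresholds, unknown labels)."""


class CohortSizeError(PanoutlierError, ValueError):
    """Reference cohort too small for a reliable outlier fence."""


class InputError(PanoutlierError, ValueError):
    """Invalid runtime input to an analysis operation."""
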