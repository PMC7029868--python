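"""Exception hierarchy shared across the package."""


class SignkinError(Exception):
    """Base class for all package-specific errors."""


class DialectError(SignkinError):
    """A file does not conform to the documented skeleton/feature dialect."""


class SingularGeometryError(SignkinError):
    """Landmark geometry is degenerate (collinear / zero-length axis)."""


class LeakageError(SignkinError):
    """Subject identity leaks between train/validation/test roles."""


class TooShortError(SignkinError):
    """A sequence is too short for cubic-spline resampling (< 4 frames)."""


class ConfigError(SignkinError):
    """Invalid configuration value."""
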