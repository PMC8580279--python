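"""Exception types shared across the package."""

__all__ = ["ConfigurationError", "FormatError", "NonEstimableError"]


class ConfigurationError(ValueError):
    """A scenario or run configuration is internally inconsistent."""


class FormatError(ValueError):
    """An input file does not conform to the summary-statistics dialect."""


class NonEstimableError(RuntimeError):
    """No causal estimate can be produced (e.g. zero usable instruments)."""
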