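"""Exception types shared across the pipeline."""


class PtsdConnError(Exception):
    """Base class for all package errors."""


class FormatError(PtsdConnError):
    """A delimited-text input violates the documented format."""


class ConfigurationError(PtsdConnError):
    """A parameter combination is invalid (e.g. band edge above Nyquist)."""


class InputError(PtsdConnError):
    """Numerically invalid input data (non-finite values, empty vectors...)."""
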