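"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a spec/config object is internally inconsistent."""


class DegenerateDataError(ValueError):
    """Raised when input data cannot support the requested computation
    (zero-variance series, single-class labels, empty matchings, ...)."""


class LeakageError(RuntimeError):
    """Raised when train and test samples share subjects."""
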