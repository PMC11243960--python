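"""Exception hierarchy shared across the package."""


class FluoromicsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FluoromicsError):
    """Input data violate a documented precondition (bad table, bad grid...)."""


class DegenerateTransientError(FluoromicsError):
    """A fluorescence transient has no usable rise (e.g. Fm == Fo)."""


class FitError(FluoromicsError):
    """A model fit could not be carried out or did not converge."""


class ConfigError(FluoromicsError):
    """Pipeline configuration is inconsistent or references missing inputs."""
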