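"""Exception hierarchy shared across the package."""


class NanoPBPKError(Exception):
    """Base class for all package errors."""


class ParameterError(NanoPBPKError):
    """A physiological or kinetic parameter violates its constraints."""


class ConfigurationError(NanoPBPKError):
    """Inconsistent or unresolvable run configuration."""


class IntegrationError(NanoPBPKError):
    """The ODE solver failed to produce a valid solution."""


class RangeError(NanoPBPKError):
    """A requested time or horizon lies outside the computed profile."""
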