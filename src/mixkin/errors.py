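"""Exception hierarchy shared across the package.

All errors raised on bad user input derive from :class:`MixkinError` so the
command-line layer can map them to a single nonzero exit code.
"""


class MixkinError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MixkinError):
    """A model or pathway is mis-specified (missing constant, bad total, ...)."""


class DomainError(MixkinError, ValueError):
    """A numeric argument is outside its physical domain."""


class UnsupportedFeatureError(MixkinError):
    """A pathway file uses a feature outside the supported subset."""


class SimulationError(MixkinError):
    """The integrator failed; carries the last good state and time."""

    def __init__(self, message, t_last=None, y_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last
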