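"""Exception hierarchy shared across the package.

Two error classes matter to callers: :class:`ConfigurationError` for invalid
settings, generator parameters or pipeline configuration, and
:class:`InputError` for malformed or inconsistent input data.  The CLI maps
them to distinct exit codes (2 and 3 respectively).
"""


class IndelCalError(Exception):
    """Base class for all indelcal errors."""


class ConfigurationError(IndelCalError):
    """Invalid settings, generator parameters or run configuration."""


class InputError(IndelCalError):
    """Malformed or internally inconsistent input data."""
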