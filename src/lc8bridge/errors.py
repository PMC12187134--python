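"""Exception hierarchy shared across the package.

Distinct classes map to distinct CLI exit codes (parse=2, config=3,
solver/convergence=4); everything derives from :class:`Lc8BridgeError`.
"""


class Lc8BridgeError(Exception):
    """Base class for all package errors."""


class DomainError(Lc8BridgeError, ValueError):
    """An input value is outside its physical/mathematical domain."""


class CompositionError(DomainError):
    """A species composition violates the trimer-architecture bounds."""


class ScheduleError(DomainError):
    """An injection schedule is inconsistent (e.g. overfills the cell)."""


class ParseError(Lc8BridgeError, ValueError):
    """A text input file does not match the documented schema."""


class ConfigError(Lc8BridgeError, ValueError):
    """A run configuration is invalid or incomplete."""


class SolverError(Lc8BridgeError, RuntimeError):
    """A numerical solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, **diagnostics):
        super().__init__(message)
        self.diagnostics = diagnostics
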