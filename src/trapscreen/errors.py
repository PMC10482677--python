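"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class TrapscreenError(Exception):
    """Base class for package errors."""


class ConfigurationError(TrapscreenError, ValueError):
    """Invalid or inconsistent configuration."""


class InputError(TrapscreenError, ValueError):
    """Malformed or inconsistent input data."""


class SimulationError(TrapscreenError, RuntimeError):
    """A simulation reached a degenerate state (e.g. empty sorted tail)."""


class CoordinateError(InputError):
    """A genomic coordinate falls outside the reference."""
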