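"""Exception hierarchy shared by all pipeline stages."""


class PedplanError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(PedplanError):
    """Invalid argument, configuration, or inconsistent input data."""


class InputError(PedplanError):
    """I/O failure: missing, ambiguous, or unreadable input."""


class PlanningError(PedplanError):
    """Screw planning failed (no channel, pedicle too narrow, ...)."""
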