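"""Exception types shared across the package."""


class RibostatError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RibostatError, ValueError):
    """A rate constant, total concentration or target is outside its domain."""


class InfeasibleStateError(RibostatError, ValueError):
    """A requested state or design would require a negative concentration."""


class DivergenceError(RibostatError, RuntimeError):
    """A numerical trajectory left the physically meaningful region.

    Raised when a concentration turns negative beyond rounding error; a
    genuinely exploding run (self-replication) is *not* an error and is
    reported on the trajectory object instead.
    """


class ConfigError(RibostatError, ValueError):
    """A scenario configuration failed validation."""
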