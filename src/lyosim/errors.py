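"""Exception hierarchy used across the package."""


class LyosimError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(LyosimError, ValueError):
    """A physical quantity or argument is outside its valid domain."""


class ConfigError(LyosimError, ValueError):
    """A configuration file or parameter set could not be resolved."""


class UnitError(ConfigError):
    """An unsupported or missing unit was encountered."""


class SolverError(LyosimError, RuntimeError):
    """A root find or least-squares fit failed to converge."""


class InfeasibleError(LyosimError, RuntimeError):
    """No operating point satisfies the active constraint set."""
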