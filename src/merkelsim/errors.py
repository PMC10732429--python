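"""Exception hierarchy (CLI exit codes map onto these)."""


class MerkelSimError(Exception):
    """Base class for package errors."""


class ConfigError(MerkelSimError):
    """Invalid configuration file, parameter or protocol."""


class RestConvergenceError(MerkelSimError):
    """The resting-state relaxation did not reach a fixed point."""


class SolverError(MerkelSimError):
    """The ODE solver failed or produced non-finite quantities."""
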