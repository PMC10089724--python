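"""Exception hierarchy for the suction-power pipeline."""


class ShpowerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ShpowerError):
    """Invalid generator or pipeline configuration."""


class DataError(ShpowerError):
    """Malformed or physically inconsistent input data."""


class KinematicsError(ShpowerError):
    """Four-bar closure failure or invalid linkage state."""


class SolverError(ShpowerError):
    """Pressure solver failed (singular system, non-convergence)."""
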