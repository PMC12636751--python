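"""Exception hierarchy for the simulator."""


class NeuritesimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NeuritesimError):
    """Invalid simulation parameters or configuration file."""


class GeometryError(NeuritesimError):
    """Degenerate or invalid geometry (coincident beads, too few beads, ...)."""


class NumericalInstabilityError(NeuritesimError):
    """The integrator produced a non-finite position or ruptured the membrane.

    Attributes
    ----------
    step : int
        Global step index at which the instability was detected.
    bead : int
        Index of the offending bead (or of one bead of the offending bond).
    """

    def __init__(self, message: str, step: int = -1, bead: int = -1):
        super().__init__(message)
        self.step = step
        self.bead = bead


class UnsupportedFormatError(NeuritesimError):
    """Trajectory file written by an incompatible format version."""


class CorruptTrajectoryError(NeuritesimError):
    """Trajectory file is internally inconsistent (truncated / mismatched frames)."""

    def __init__(self, message: str, frame: int = -1):
        super().__init__(message)
        self.frame = frame
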