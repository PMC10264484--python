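"""Exception hierarchy for metamorph."""


class MetamorphError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(MetamorphError):
    """A synthetic-trajectory specification violates its invariants."""


class TrajectoryFormatError(MetamorphError):
    """A trajectory file is malformed (inconsistent models, bad values)."""


class SelectionError(MetamorphError):
    """An atom selection matched nothing."""


class SuperpositionError(MetamorphError):
    """Least-squares fitting failed (degenerate/collinear reference)."""


class InsufficientDataError(MetamorphError):
    """Too few frames for the requested statistic."""


class DegenerateGridError(MetamorphError):
    """A grid dimension has zero sample range."""


class EmptyLandscapeError(MetamorphError):
    """All grid cells were dropped by the occupancy threshold."""


class IncompatibleConformersError(MetamorphError):
    """Conformer thermodynamics differ in dimensionality or temperature."""


class UnsupportedTopologyError(MetamorphError):
    """The trajectory lacks the atoms an operation requires."""


class StudyError(MetamorphError):
    """A multi-system study failed; carries the system and stage."""

    def __init__(self, message: str, system: str | None = None,
                 stage: str | None = None):
        super().__init__(message)
        self.system = system
        self.stage = stage
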