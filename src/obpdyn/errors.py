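"""Exception hierarchy shared across the toolkit."""


class ObpdynError(Exception):
    """Base class for all toolkit errors."""


class PDBParseError(ObpdynError):
    """A fixed-width PDB record could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyStructureError(ObpdynError):
    """File contained no ATOM records."""


class TopologyMismatchError(ObpdynError):
    """Trajectory atom count disagrees with the structure."""


class PartialFileError(ObpdynError):
    """Trajectory file ended mid-frame; ``frames_read`` frames were recovered."""

    def __init__(self, message: str, frames_read: int = 0):
        super().__init__(message)
        self.frames_read = frames_read


class EmptySelectionError(ObpdynError):
    """A region resolved to zero atoms/residues."""


class DegenerateFitError(ObpdynError):
    """Superposition input was rank-deficient or too small."""


class DegeneratePlaneError(ObpdynError):
    """The three disulfide midpoints are collinear; no plane is defined."""


class InsufficientFramesError(ObpdynError):
    """Operation requires more trajectory frames than provided."""


class SingularGeometryError(ObpdynError):
    """Coincident atoms make an energy/geometry term undefined."""


class LookupError_(ObpdynError):
    """Requested atom label does not exist in the structure."""
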