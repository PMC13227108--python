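"""Exception hierarchy for dnaforge."""


class DnaForgeError(Exception):
    """Base class for all dnaforge errors."""


class InvalidFrameError(DnaForgeError):
    """A reference frame failed orthonormality / handedness validation."""


class AmbiguousRotationError(DnaForgeError):
    """A 180-degree relative rotation has no unique axis; the caller must perturb."""


class RotationOutOfRangeError(DnaForgeError):
    """A rotation vector with magnitude >= 180 degrees is not a principal rotation."""


class TooFewPointsError(DnaForgeError):
    """Fewer than four control points were supplied for spline interpolation."""


class DegenerateInputError(DnaForgeError):
    """Geometrically degenerate input (duplicate points, zero tangent, ...)."""


class WritheUndefinedError(DnaForgeError):
    """Writhe requested on an open chain without the allow-open override."""


class TopologyError(DnaForgeError):
    """Operation incompatible with the structure's topology (open/closed)."""


class UnknownBaseError(DnaForgeError):
    """Sequence letter outside the supported nucleobase alphabet."""


class MissingTemplateError(DnaForgeError):
    """No atomic template registered for a nucleobase code."""


class NotMethylatableError(DnaForgeError):
    """Methylation requested on a base that is neither C nor G."""


class EditError(DnaForgeError):
    """Invalid structure-editing request (bad index, circular input, ...)."""


class MinimizationError(DnaForgeError):
    """Monte Carlo relaxation cannot run on this input."""


class IOFormatError(DnaForgeError):
    """Malformed frame-array / control-point / PDB input."""
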