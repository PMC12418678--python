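"""Exception hierarchy shared by the mmfit modules."""


class MmfitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MmfitError, ValueError):
    """An input object violates a documented invariant."""


class ParseError(MmfitError, ValueError):
    """A text input (databank, cube, model file ...) is malformed."""


class DatabankLookupError(MmfitError, KeyError):
    """An element or deformation level is missing from the databank."""


class CapabilityError(MmfitError, ValueError):
    """A requested multipole level exceeds what the databank supports."""


class FrameError(MmfitError, ValueError):
    """A local coordinate frame cannot be constructed."""


class ConstraintError(MmfitError, ValueError):
    """Parameter ties/fixes are inconsistent."""


class AlignmentError(MmfitError, ValueError):
    """Two objects that must share an hkl set or grid spec do not."""


class DegenerateInputError(MmfitError, ValueError):
    """Input is degenerate (zero variance, zero norm ...)."""


class RankDeficiencyError(MmfitError, RuntimeError):
    """The least-squares normal matrix is singular.

    ``null_parameters`` names the parameter slots spanning the null space.
    """

    def __init__(self, message, null_parameters=()):
        super().__init__(message)
        self.null_parameters = tuple(null_parameters)


class ResolutionError(MmfitError, ValueError):
    """A grid is too coarse (Nyquist) for the requested reflections."""


class EmptySurfaceError(MmfitError, ValueError):
    """The requested iso-level lies outside the field's value range."""


class OutOfBoundsError(MmfitError, ValueError):
    """A surface point falls outside the sampled grid volume."""


class InputError(MmfitError, ValueError):
    """A pipeline input component is missing or inconsistent."""
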