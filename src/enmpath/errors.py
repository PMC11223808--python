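"""Exception hierarchy for the path-generation pipeline.

Each pipeline stage raises a specific subclass of :class:`EnmPathError`
so that the command-line driver can map failures to exit codes and
print a remedy hint alongside the stage name.
"""


class EnmPathError(Exception):
    """Base class for all package-specific errors."""


class StructureFormatError(EnmPathError):
    """The input file could not be parsed as PDB or mmCIF."""


class EmptyStructureError(EnmPathError):
    """No atoms remain after filtering hydrogens and heteroatoms."""


class SizeMismatchError(EnmPathError):
    """Coordinate arrays or frames disagree in atom count."""


class MixedAlphabetError(EnmPathError, TypeError):
    """Sequences from different polymer alphabets cannot be aligned."""


class NoCorrespondenceError(EnmPathError):
    """No chain pair aligned with a positive score."""


class TooFewAtomsError(EnmPathError):
    """Fewer common atoms than the rigid-body modes require."""


class DegenerateGeometryError(EnmPathError):
    """Point set is collinear/coplanar where 3-D geometry is needed."""


class IsolatedAtomError(EnmPathError):
    """An atom has no neighbour in the elastic network."""


class SingularGeometryError(EnmPathError):
    """Coincident atoms make a distance-based term singular."""


class UnsupportedInputError(EnmPathError):
    """Input violates a model restriction (e.g. Go model on nucleic acids)."""


class NoCrossingError(EnmPathError):
    """The two wells never meet with the requested free-energy offset."""


class SolverError(EnmPathError):
    """An iterative solver failed to converge."""
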