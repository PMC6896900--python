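"""Exception hierarchy shared across the analysis modules."""


class NucdynError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(NucdynError):
    """Inconsistent or invalid complex topology."""


class MissingChainError(TopologyError):
    """A chain required by a variant deletion is absent."""


class VariantStateError(TopologyError):
    """A dimer deletion was applied to an already-reduced topology."""


class ClassificationError(TopologyError):
    """A histone residue falls in neither the core nor a tail region."""


class IncompleteResidueError(TopologyError):
    """A residue lacks the representative atom (C1' or CA) a mask requires."""


class FormatError(NucdynError):
    """A structure or trajectory file could not be parsed."""


class TopologyMismatchError(NucdynError):
    """A trajectory's atom count disagrees with the topology."""


class WindowError(NucdynError):
    """An analysis window resolves to no frames of some trial."""


class DegenerateGeometryError(NucdynError):
    """Too few or collinear atoms for a rigid-body superposition."""


class InputError(NucdynError):
    """Mismatched or otherwise invalid operation inputs."""
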