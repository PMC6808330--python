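"""Exception hierarchy shared across the package."""


class CyclodelimError(Exception):
    """Base class for all package-specific errors."""


class InputError(CyclodelimError, ValueError):
    """Invalid user-supplied data (bad identifiers, inconsistent tables...)."""


class AlignmentFormatError(CyclodelimError, ValueError):
    """Malformed alignment file (ragged rows, unparsable records)."""


class UndefinedDistanceError(CyclodelimError, ValueError):
    """A pairwise distance cannot be computed (no comparable sites, or the
    distance correction is undefined because of saturation)."""


class NonConvexPartitionError(CyclodelimError, ValueError):
    """A partition whose species spanning subtrees share an edge on the tree."""


class UnrootedTreeError(CyclodelimError, ValueError):
    """A Newick tree without a resolved root where a rooted tree is required."""


class DegenerateInputError(CyclodelimError, ValueError):
    """Input that is formally valid but carries no usable signal
    (e.g. a tree whose branch lengths are all zero)."""
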