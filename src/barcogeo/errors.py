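"""Exception hierarchy.

Every failure mode the readers, distance code and delimitation logic can hit
maps to one of these, so callers can catch the base class or a specific one.
"""


class BarcogeoError(Exception):
    """Base class for all package errors."""


class EmptyInputError(BarcogeoError):
    pass


class AlignmentShapeError(BarcogeoError):
    """Sequences of unequal length in a supposedly aligned matrix."""


class DuplicateIdError(BarcogeoError):
    pass


class SchemaError(BarcogeoError):
    """Required column missing or unparseable in a metadata/partition table."""


class CoordinateRangeError(BarcogeoError):
    """Latitude outside [-90, 90] or longitude outside [-180, 180]."""


class PartitionConflictError(BarcogeoError):
    """A specimen listed with two different group labels."""


class IntegrityError(BarcogeoError):
    """Identifier sets of two objects that must match do not."""


class UnassignedMorphospeciesError(IntegrityError):
    """A specimen reached geographic delimitation without a morphospecies."""


class ParseError(BarcogeoError):
    """Malformed newick or other structured text."""


class ParameterError(BarcogeoError):
    """Out-of-range configuration value."""


class IncomparablePairError(BarcogeoError):
    """A sequence pair with no site where both have an unambiguous base."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(f"no comparable sites for pairs: {self.pairs}")


class SaturationError(BarcogeoError):
    """K2P log argument <= 0: the pair is too divergent for the correction."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(f"K2P saturation for pairs: {self.pairs}")


class RootingError(BarcogeoError):
    """Monophyly asked on an unrooted tree without an outgroup."""


class ConfigurationError(BarcogeoError):
    """Simulation configuration unsatisfiable (e.g. range spacing)."""
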