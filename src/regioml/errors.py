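"""Exception hierarchy for regioml.

All package-specific failures derive from :class:`RegiomlError` so callers
can catch one base class; the CLI maps them onto exit codes.
"""


class RegiomlError(Exception):
    """Base class for all regioml errors."""


class ParseError(RegiomlError):
    """SMILES or reaction SMILES could not be parsed."""


class MappingError(RegiomlError):
    """Atom-map numbers are invalid (e.g. duplicated within a reactant set)."""


class SchemaError(RegiomlError):
    """A CSV table is missing required columns."""


class AlignmentError(RegiomlError):
    """Descriptor rows do not align with the molecule's heavy-atom count."""


class MissingDescriptor(RegiomlError):
    """A required atom/bond descriptor is absent from the table."""


class UnresolvedMapNumber(RegiomlError):
    """A candidate's atom-map number does not resolve to a reactant atom."""


class LengthMismatch(RegiomlError):
    """Vectors of unequal length were compared."""


class EmptyDataset(RegiomlError):
    """A training set is empty after filtering."""


class DegenerateRecord(RegiomlError):
    """A reaction record with fewer than two candidates cannot be ranked."""


class NonFiniteLoss(RegiomlError):
    """Training produced a NaN/Inf loss."""


class NoChangeDetected(RegiomlError):
    """A mapped reaction has identical reactant and product connectivity."""


class UnmappedProductAtom(RegiomlError):
    """A product atom lacks an atom-map number."""


class NoMatch(RegiomlError):
    """A reaction template does not apply to the given reactants."""


class RecordedProductNotAmongCandidates(RegiomlError):
    """The recorded product is not one of the enumerated candidates."""


class InsufficientData(RegiomlError):
    """Not enough records for the requested split."""


class UnsupportedMolecule(RegiomlError):
    """Molecule outside the supported domain (e.g. net-charged species)."""
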