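"""Exception hierarchy for melanomorph."""


class MelanomorphError(Exception):
    """Base class for all package errors."""


class SchemaError(MelanomorphError):
    """A required column or field is missing from an input file."""


class ValidationError(MelanomorphError):
    """Input rows violate a table invariant; message lists offending rows."""


class TreeError(MelanomorphError):
    """A tree is malformed or incompatible with the data."""


class UnresolvableTaxonError(TreeError):
    """Species cannot be placed in the reference tree by genus."""


class DegenerateGeometryError(MelanomorphError):
    """Too few or affinely dependent points for a volume computation."""


class DegenerateVariableError(MelanomorphError):
    """A variable is constant (or a level unobserved) at fit time."""
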