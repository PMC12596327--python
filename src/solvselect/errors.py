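"""Exception hierarchy shared across the screening and recovery modules."""


class SolvselectError(Exception):
    """Base class for all solvselect errors."""


class SchemaError(SolvselectError):
    """A table is missing mandatory columns or columns do not match a model."""


class CatalogValidationError(SolvselectError):
    """A catalog violates an invariant (duplicate names, missing boiling points...)."""


class IncompleteDataError(SolvselectError):
    """A solvent lacks the parameters required by the requested computation."""


class SolventLookupError(SolvselectError, KeyError):
    """A named solvent is absent from the catalog or result set."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class IncompleteDesignError(SolvselectError):
    """An experimental design is missing a required group (e.g. a spike timing)."""
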