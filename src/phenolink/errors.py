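"""Exception hierarchy for phenolink."""


class PhenolinkError(Exception):
    """Base class for all phenolink-specific errors."""


class OboFormatError(PhenolinkError):
    """Malformed OBO input (duplicate ids, missing names, bad stanzas)."""


class DanglingReferenceError(OboFormatError):
    """An ``is_a`` target is not defined anywhere in the file."""


class OntologyCycleError(OboFormatError):
    """The parent relation contains a cycle; ``path`` lists one offending loop."""

    def __init__(self, path):
        self.path = list(path)
        super().__init__("cycle in is_a relation: " + " -> ".join(self.path))


class UnknownConceptError(PhenolinkError, KeyError):
    """A concept id does not resolve within the ontology."""

    def __str__(self):  # KeyError quotes its args; keep a plain message
        return self.args[0] if self.args else ""


class ObsoleteConceptError(UnknownConceptError):
    """The concept exists but is obsolete and excluded from computation."""


class TableFormatError(PhenolinkError):
    """Malformed association table or mapping TSV."""


class IntegrityError(PhenolinkError):
    """A link does not resolve against the knowledge base's records or concepts."""


class StorageError(PhenolinkError):
    """A knowledge-base file is missing or does not match the expected schema."""


class UnsupportedSizeError(PhenolinkError):
    """The exact null-overlap oracle was asked for a problem size it refuses."""


class FixtureParamError(PhenolinkError):
    """Invalid synthetic-fixture parameters."""
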